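"""trfscan: discovery and downstream analysis of tRNA-derived small RNAs.

The package re-implements, desk-scale and fully testable, the analysis
chain that identifies an anomalous read-length peak in small-RNA sequencing
data, decomposes it into constituent sequences, traces the dominant
sequence to multi-copy tRNA genes, quantifies its group difference,
predicts its complementarity targets, and integrates the predictions with
proteome and metabolome screens.
"""

from importlib import resources
from pathlib import Path

__version__ = "0.1.0"


def reference_loci_path() -> Path:
    """Path of the packaged glycine tRNA gene locus table (1-based closed)."""
    return Path(str(resources.files("trfscan") / "data" / "trnag_loci.tsv"))
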