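#!/usr/bin/env python
"""Place the dominant peak sequence on the genome, intersect the hits with
the tRNA gene annotation and class each placement (tRF-5/half-5/...)."""

import pandas as pd

from _common import SCRATCH_RUN, parse_seed, publish, study_config
from trfscan.pipeline import run_stage

cfg = study_config(parse_seed())
summary = run_stage("annotate", cfg)
publish("fragment_hits.tsv")
hits = pd.read_csv(SCRATCH_RUN / "fragment_hits.tsv", sep="\t")
print(f"{len(hits)} genomic placements of the dominant sequence, "
      f"classes {sorted(hits['fragment_class'].unique())}, "
      f"reported label {sorted(hits['reported_label'].unique())}")
print(hits.groupby("gene_name").size().to_string())
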