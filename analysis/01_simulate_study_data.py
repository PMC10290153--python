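#!/usr/bin/env python
"""Generate the synthetic study: genome, tRNA loci, small-RNA reads for
three coarse-wool and three fine-wool lambs at 1e5 reads each, plus the
proteome, metabolome, qPCR and 3'UTR inputs downstream stages consume."""

from _common import parse_seed, publish, study_config
from trfscan.pipeline import run_stage

seed = parse_seed()
cfg = study_config(seed)
summary = run_stage("simulate", cfg, force=True)
publish("loci.tsv", "samples.tsv")
print(f"simulated {summary['n_samples']} samples; "
      f"{summary['n_loci']} tRNA gene copies planted on the toy genome")
print(f"run directory: {cfg.outdir}")
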