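#!/usr/bin/env python
"""Scan the fragment against every 3'UTR with the seed-weighted
complementarity aligner and call target genes."""

from _common import SCRATCH_RUN, parse_seed, publish, study_config
from trfscan.pipeline import run_stage

cfg = study_config(parse_seed())
summary = run_stage("targets", cfg)
publish("target_hits.tsv", "predicted_genes.txt")
print(f"{summary.get('n_predicted_genes', 'cached')} genes carry at least one "
      "surviving complementarity site")
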