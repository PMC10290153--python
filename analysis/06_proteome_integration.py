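#!/usr/bin/env python
"""Call differential proteins (fold >1.20 or <0.83, p<0.05), intersect the
down-regulated set with the predicted targets, and test pathway
over-representation of the overlap."""

import json

import pandas as pd

from _common import SCRATCH_RUN, parse_seed, publish, study_config
from trfscan.pipeline import run_stage

cfg = study_config(parse_seed())
run_stage("proteome", cfg)
run_stage("integrate", cfg)
publish("deps.tsv", "overlap.json", "ora.tsv")
ov = json.loads((SCRATCH_RUN / "overlap.json").read_text())
print(f"{ov['n_overlap']} of {ov['n_down_deps']} down-regulated proteins "
      f"({ov['pct_of_down']:.2f}%) are predicted targets "
      f"(hypergeometric p = {ov['hypergeom_p']:.2e})")
ora = pd.read_csv(SCRATCH_RUN / "ora.tsv", sep="\t")
print("top enriched sets:")
print(ora.head(3)[["set_id", "k", "K", "p", "q"]].to_string(index=False))
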