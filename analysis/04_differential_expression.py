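#!/usr/bin/env python
"""Quantify the four 32nt peak sequences per sample, test the group
difference, and compute qPCR 2^-ddCt relative expression for the fragment
(vs U6-style small-RNA reference) and the intact tRNA (vs actin-style
reference)."""

import json

import pandas as pd

from _common import SCRATCH_RUN, parse_seed, publish, study_config
from trfscan.pipeline import run_stage

cfg = study_config(parse_seed())
run_stage("diff", cfg)
publish("diff.tsv", "qpcr.json")
diff = pd.read_csv(SCRATCH_RUN / "diff.tsv", sep="\t")
top = diff.iloc[0]
print(f"dominant fragment: coarse/fine fold {top['fold']:.2f}, "
      f"p = {top['p_value']:.2e}")
q = json.loads((SCRATCH_RUN / "qpcr.json").read_text())
print(f"qPCR fragment assay: coarse RQ {q['trf']['coarse']:.2f} (fine = 1)")
print(f"qPCR intact-tRNA assay: fine/coarse fold "
      f"{1 / q['trna']['coarse']:.2f}")
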