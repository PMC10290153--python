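#!/usr/bin/env python
"""Aggregate every stage's key numbers into one JSON report."""

import json

from _common import SCRATCH_RUN, parse_seed, publish, study_config
from trfscan.pipeline import run_stage

cfg = study_config(parse_seed())
run_stage("metabolome", cfg)   # in-pipeline metabolome (n = 3 per group)
run_stage("report", cfg)
publish("report.json")
r = json.loads((SCRATCH_RUN / "report.json").read_text())
print(json.dumps({
    "peak_lengths": [p["length"] for p in r["peak_calls"]],
    "fragment_hits": r["fragment_annotation"],
    "overlap_pct_of_down": round(r["overlap"]["pct_of_down"], 2),
    "qpcr": {k: round(v["coarse"], 3) for k, v in r["qpcr"].items()},
}, indent=1))
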