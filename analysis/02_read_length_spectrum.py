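#!/usr/bin/env python
"""Length-filter the reads (18-41 nt), build per-sample length spectra and
screen for anomalous peaks between the coarse and fine wool groups, then
decompose the called peak into its constituent sequences."""

import json

from _common import SCRATCH_RUN, parse_seed, publish, study_config
from trfscan.pipeline import run_stage

cfg = study_config(parse_seed())
run_stage("spectrum", cfg)
run_stage("decompose", cfg)
publish("spectra.tsv", "peaks.json", "composition.json")

peaks = json.loads((SCRATCH_RUN / "peaks.json").read_text())
for p in peaks:
    print(f"anomalous peak at {p['length']} nt: "
          f"coarse/fine fold {p['group_fold']:.2f}, p = {p['p_value']:.2e}")
comp = json.loads((SCRATCH_RUN / "composition.json").read_text())
for grp in ("coarse", "fine"):
    dom = comp[grp]["dominant"]
    print(f"{grp}: dominant 32nt sequence at {100 * dom['fraction']:.1f}% "
          f"of peak reads")
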