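"""Shared plumbing for the numbered analysis drivers.

The heavy per-sample artefacts (FASTQ, FASTA) live under scratch/; the small
tables and summaries each driver reports are copied into results/.
"""

import argparse
import shutil
from pathlib import Path

from trfscan.config import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH_RUN = ROOT / "scratch" / "study_run"
RESULTS = ROOT / "results"


def study_config(seed: int = 1) -> PipelineConfig:
    """The study conditions: depth 1e5, three lambs per wool-type group."""
    return PipelineConfig.from_dict({
        "seed": seed,
        "outdir": str(SCRATCH_RUN),
    })


def parse_seed() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    return ap.parse_args().seed


def publish(*names: str) -> None:
    """Copy small run outputs into results/."""
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        shutil.copy(SCRATCH_RUN / name, RESULTS / name)
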