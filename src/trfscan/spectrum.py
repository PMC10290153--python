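"""Read-length spectra, anomalous-peak detection and peak decomposition.

Small-RNA libraries show a canonical miRNA peak around 22 nt.  The screen
implemented here looks for additional read-length peaks that differ between
two groups of samples: for every length outside the canonical window that is
a local maximum of a group-mean RPM spectrum and reaches a configurable
fraction of the canonical peak, a two-sample test on per-sample RPM and a
group fold gate decide whether the length is called anomalous.  A called
peak can then be decomposed into its constituent unique sequences to find a
dominant fragment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_MAX_LEN, DEFAULT_MIN_LEN
from .errors import DataError
from .seqio import read_fastq_sequences

RPM_SCALE = 1_000_000


@dataclass
class ReadSet:
    """Reads of one sample with its group label."""

    sample_id: str
    group: str
    reads: list[str]

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class LengthSpectrum:
    """Per-sample read counts by length over a closed window."""

    sample_id: str
    group: str
    counts: dict[int, int]
    total_retained: int
    normalized: dict[int, float]  # reads per million retained
    empty: bool = False


@dataclass
class PeakCall:
    """An anomalous length with its group statistics."""

    length: int
    mean_height: dict[str, float]  # group -> mean RPM
    group_fold: float              # first group over second
    p_value: float
    ratio_to_canonical: float
    q_value: Optional[float] = None


@dataclass
class PeakComposition:
    """Unique-sequence breakdown of all reads at one length."""

    length: int
    entries: list[tuple[str, int, float]]  # (sequence, count, fraction)
    dominant: Optional[tuple[str, int, float]] = None


@dataclass
class PeakParams:
    """Gates of the anomalous-peak screen."""

    canonical_window: tuple[int, int] = (20, 24)
    min_ratio: float = 0.25   # height vs canonical peak, in >=1 group
    alpha: float = 0.05
    min_fold: float = 2.0     # either direction
    bh: bool = False          # optional BH correction across tested lengths


def load_reads(fastq_path: str | Path, sample_id: str, group: str) -> ReadSet:
    """Read one FASTQ file into a ReadSet; N-containing reads are retained."""
    return ReadSet(sample_id, group, read_fastq_sequences(fastq_path))


def filter_by_length(rs: ReadSet, min_len: int = DEFAULT_MIN_LEN,
                     max_len: int = DEFAULT_MAX_LEN) -> ReadSet:
    """Keep reads with min_len <= length <= max_len (closed window)."""
    if min_len > max_len:
        raise DataError(f"min_len {min_len} > max_len {max_len}")
    return ReadSet(rs.sample_id, rs.group,
                   [r for r in rs.reads if min_len <= len(r) <= max_len])


def length_spectrum(rs: ReadSet,
                    window: tuple[int, int] = (DEFAULT_MIN_LEN, DEFAULT_MAX_LEN),
                    ) -> LengthSpectrum:
    """Tally reads by length over every length in the window (zeros kept)."""
    lo, hi = window
    tally = Counter(len(r) for r in rs.reads if lo <= len(r) <= hi)
    counts = {length: tally.get(length, 0) for length in range(lo, hi + 1)}
    total = sum(counts.values())
    if total > 0:
        normalized = {k: v * RPM_SCALE / total for k, v in counts.items()}
        empty = False
    else:
        normalized = {k: 0.0 for k in counts}
        empty = True
    return LengthSpectrum(rs.sample_id, rs.group, counts, total, normalized, empty)


def spectrum_from_counts(sample_id: str, group: str,
                         counts: dict[int, int]) -> LengthSpectrum:
    """Build a LengthSpectrum directly from a length tally."""
    total = sum(counts.values())
    if total > 0:
        normalized = {k: v * RPM_SCALE / total for k, v in counts.items()}
    else:
        normalized = {k: 0.0 for k in counts}
    return LengthSpectrum(sample_id, group, dict(counts), total, normalized,
                          empty=total == 0)


def _ttest_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided plain (pooled-variance) t-test p.

    The pooled test is exact at the small replicate counts typical of
    small-RNA studies.  Degenerate zero-variance equal comparisons give
    p = 1 by convention.
    """
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def detect_anomalous_peaks(spectra: Sequence[LengthSpectrum],
                           params: PeakParams = PeakParams(),
                           groups: Optional[tuple[str, str]] = None,
                           return_all: bool = False) -> list[PeakCall]:
    """Screen every non-canonical length for a group difference.

    A length is called when (i) it is a local maximum of a group-mean RPM
    spectrum, (ii) its mean height reaches ``min_ratio`` of the canonical
    peak in at least one group, (iii) the plain two-sample t-test on per-sample
    RPM gives p < alpha, and (iv) the group fold is >= min_fold in either
    direction.  ``return_all=True`` skips gates and returns the statistics
    for every non-canonical length (used for calibration checks).  Calls are
    sorted by ascending p.
    """
    if groups is None:
        seen: list[str] = []
        for s in spectra:
            if s.group not in seen:
                seen.append(s.group)
        if len(seen) != 2:
            raise DataError(f"need exactly two groups, found {seen}")
        groups = (seen[0], seen[1])
    g_a, g_b = groups
    by_group = {g: [s for s in spectra if s.group == g] for g in groups}
    for g, members in by_group.items():
        if len(members) < 2:
            raise DataError(f"group '{g}' has {len(members)} samples; need >= 2")

    lengths = sorted(spectra[0].normalized)
    mat = {g: np.array([[s.normalized[L] for L in lengths] for s in by_group[g]])
           for g in groups}
    mean = {g: mat[g].mean(axis=0) for g in groups}
    lo_c, hi_c = params.canonical_window
    canon_idx = [i for i, L in enumerate(lengths) if lo_c <= L <= hi_c]
    if not canon_idx:
        raise DataError("canonical window lies outside the spectrum window")
    canonical = {g: float(mean[g][canon_idx].max()) for g in groups}

    calls: list[PeakCall] = []
    for i, L in enumerate(lengths):
        if lo_c <= L <= hi_c:
            continue
        is_local_max = any(_local_max(mean[g], i) for g in groups)
        ratio = max(
            (mean[g][i] / canonical[g]) if canonical[g] > 0 else np.inf
            for g in groups
        )
        if not return_all and (not is_local_max or ratio < params.min_ratio):
            continue
        a, b = mat[g_a][:, i], mat[g_b][:, i]
        p = _ttest_p(a, b)
        ma, mb = float(a.mean()), float(b.mean())
        if mb > 0:
            fold = ma / mb
        elif ma > 0:
            fold = np.inf
        else:
            fold = 1.0
        call = PeakCall(
            length=L,
            mean_height={g_a: ma, g_b: mb},
            group_fold=fold,
            p_value=p,
            ratio_to_canonical=float(ratio),
        )
        if return_all:
            calls.append(call)
        elif p < params.alpha and (fold >= params.min_fold
                                   or fold <= 1.0 / params.min_fold):
            calls.append(call)
    if params.bh and calls:
        q = multipletests([c.p_value for c in calls], method="fdr_bh")[1]
        for c, qv in zip(calls, q):
            c.q_value = float(qv)
    calls.sort(key=lambda c: (c.p_value, c.length))
    return calls


def _local_max(v: np.ndarray, i: int) -> bool:
    left = v[i - 1] if i > 0 else -np.inf
    right = v[i + 1] if i < len(v) - 1 else -np.inf
    return v[i] > left and v[i] > right


def decompose_peak(readsets: Iterable[ReadSet], length: int,
                   ) -> dict[str, PeakComposition]:
    """Unique-sequence composition of reads at one length, per group + pooled.

    Sequences containing N are excluded (they cannot be genome-matched
    exactly).  Entries are sorted by count descending, ties broken
    lexicographically; fractions sum to 1 within each composition.
    """
    tallies: dict[str, Counter] = {"pooled": Counter()}
    for rs in readsets:
        tallies.setdefault(rs.group, Counter())
        for r in rs.reads:
            if len(r) == length and "N" not in r:
                tallies[rs.group][r] += 1
                tallies["pooled"][r] += 1
    out: dict[str, PeakComposition] = {}
    for key, tally in tallies.items():
        total = sum(tally.values())
        entries = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        rows = [(seq, n, n / total) for seq, n in entries] if total else []
        out[key] = PeakComposition(length, rows, rows[0] if rows else None)
    return out
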