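"""Fragment quantification, group testing and qPCR relative expression.

Counts are exact-sequence tallies per sample (a desk-scale stand-in for a
feature-count step), normalised to reads per million retained reads before a
two-sided Welch t-test per fragment.  qPCR relative expression follows the
2^-ddCt convention: dCt = Ct_target - Ct_reference per sample, ddCt is the
difference of group-mean dCt versus the control group, and the relative
quantity is 2^-ddCt with the control at 1 by definition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .spectrum import RPM_SCALE, ReadSet


@dataclass
class CountMatrix:
    """Integer counts of target sequences per sample.

    ``lib_sizes`` carries the retained-read total of each sample so RPM
    normalisation reflects library size, not just assigned reads.
    """

    counts: pd.DataFrame          # rows: sequence/locus ids, cols: samples
    groups: dict[str, str]        # sample -> group label
    lib_sizes: dict[str, int]     # sample -> retained reads

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise DataError("counts must be non-negative")
        for col in self.counts.columns:
            if col not in self.groups:
                raise DataError(f"sample {col} has no group label")
            if col not in self.lib_sizes:
                raise DataError(f"sample {col} has no library size")
            if int(self.counts[col].sum()) > self.lib_sizes[col]:
                raise DataError(
                    f"sample {col}: assigned counts exceed retained reads")


@dataclass
class DiffResult:
    id: str
    mean_a: float      # RPM, first group
    mean_b: float      # RPM, second group
    fold: float        # mean_a / mean_b; inf sentinel when mean_b == 0
    fold_defined: bool
    t_stat: float
    p_value: float


def build_count_matrix(readsets: Sequence[ReadSet],
                       target_sequences: Sequence[str]) -> CountMatrix:
    """Exact-occurrence counts of each target sequence in each sample."""
    if len(set(target_sequences)) != len(target_sequences):
        raise DataError("duplicate target sequences")
    cols = {}
    groups, lib_sizes = {}, {}
    for rs in readsets:
        tally = Counter(rs.reads)
        cols[rs.sample_id] = [tally.get(t, 0) for t in target_sequences]
        groups[rs.sample_id] = rs.group
        lib_sizes[rs.sample_id] = len(rs.reads)
    counts = pd.DataFrame(cols, index=list(target_sequences))
    return CountMatrix(counts, groups, lib_sizes)


def rpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Reads-per-million-retained normalisation of the count matrix."""
    out = cm.counts.astype(float).copy()
    for col in out.columns:
        lib = cm.lib_sizes[col]
        out[col] = out[col] * RPM_SCALE / lib if lib > 0 else 0.0
    return out


def group_ttest(cm: CountMatrix,
                groups: Optional[tuple[str, str]] = None,
                normalize: bool = True,
                equal_var: bool = False) -> list[DiffResult]:
    """Per-row two-sided t-test (Welch by default) on normalised counts.

    Fold is mean(first group)/mean(second group); rows where both groups
    have zero variance and equal means get p = 1.  Rows with a zero
    second-group mean carry an infinite-fold sentinel with
    ``fold_defined=False``.
    """
    if groups is None:
        seen: list[str] = []
        for col in cm.counts.columns:
            g = cm.groups[col]
            if g not in seen:
                seen.append(g)
        if len(seen) != 2:
            raise DataError(f"need exactly two groups, found {seen}")
        groups = (seen[0], seen[1])
    g_a, g_b = groups
    cols_a = [c for c in cm.counts.columns if cm.groups[c] == g_a]
    cols_b = [c for c in cm.counts.columns if cm.groups[c] == g_b]
    for g, cols in ((g_a, cols_a), (g_b, cols_b)):
        if len(cols) < 2:
            raise ConfigError(f"group '{g}' has {len(cols)} samples; need >= 2")
    mat = rpm_normalize(cm) if normalize else cm.counts.astype(float)
    out: list[DiffResult] = []
    for rid, row in mat.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        ma, mb = float(a.mean()), float(b.mean())
        if a.var() == 0 and b.var() == 0:
            t, p = 0.0, (1.0 if ma == mb else 0.0)
        else:
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            t, p = float(res.statistic), float(res.pvalue)
        if mb > 0:
            fold, defined = ma / mb, True
        elif ma > 0:
            fold, defined = float("inf"), False
        else:
            fold, defined = 1.0, True
        out.append(DiffResult(str(rid), ma, mb, fold, defined, t, p))
    return out


def ddct(qpcr: pd.DataFrame, control_group: str) -> dict[str, float]:
    """2^-ddCt relative expression per group, control fixed at 1.

    The table needs columns ``group``, ``ct_target``, ``ct_reference``.
    Returns {group: relative quantity}; also includes the ddCt value of the
    case group under key ``"ddct"``.
    """
    for col in ("group", "ct_target", "ct_reference"):
        if col not in qpcr.columns:
            raise DataError(f"qPCR table missing column '{col}'")
    if qpcr["ct_reference"].isna().any():
        raise DataError("missing reference Ct values")
    groups = list(dict.fromkeys(qpcr["group"]))
    if control_group not in groups:
        raise DataError(f"control group '{control_group}' not in table")
    if len(groups) != 2:
        raise DataError(f"need exactly two groups, found {groups}")
    case = next(g for g in groups if g != control_group)
    dct = qpcr["ct_target"] - qpcr["ct_reference"]
    mean_dct = dct.groupby(qpcr["group"]).mean()
    ddct_val = float(mean_dct[case] - mean_dct[control_group])
    return {control_group: 1.0, case: float(2.0 ** (-ddct_val)),
            "ddct": ddct_val}


def diff_results_frame(results: Iterable[DiffResult]) -> pd.DataFrame:
    rows = [{"id": r.id, "mean_a": r.mean_a, "mean_b": r.mean_b,
             "fold": r.fold if np.isfinite(r.fold) else np.inf,
             "fold_defined": r.fold_defined,
             "t_stat": r.t_stat, "p_value": r.p_value}
            for r in results]
    return pd.DataFrame(rows)
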