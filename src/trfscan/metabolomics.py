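"""Chemometric screen for differential metabolites.

The processing order is fixed: prevalence filter (a metabolite is kept when
more than half of its measurements are nonzero in at least one group) ->
total-intensity normalisation (each sample scaled to the median column sum)
-> Pareto scaling per metabolite ((x - mean) / sqrt(sd)) -> unsupervised PCA
with QC assessment and supervised PLS-DA -> the screen itself, a sequential
gate of VIP > 1 followed by a two-sided t-test at alpha = 0.05 on the
VIP-passing subset.

The discriminant model is plain PLS-DA (NIPALS, one binary response) with
the standard VIP statistic; with a single response the VIP ranking serves
the same role as in the orthogonal variant, whose orthogonal-variation
filtering is deliberately not implemented (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import QC_ROLE
from .errors import ConfigError, DataError


@dataclass
class VipScores:
    """Per-metabolite variable importance in projection; mean(VIP^2) = 1."""

    scores: pd.Series
    n_components: int


def _group_cols(roles: dict[str, str], cols: Sequence[str],
                include_qc: bool = False) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for c in cols:
        role = roles.get(c)
        if role is None:
            raise DataError(f"sample {c} has no role/group assignment")
        if role == QC_ROLE and not include_qc:
            continue
        out.setdefault(role, []).append(c)
    return out


def prevalence_filter(table: pd.DataFrame, roles: dict[str, str],
                      min_fraction: float = 0.5) -> pd.DataFrame:
    """Keep metabolites with > min_fraction nonzero values in >= 1 group.

    QC columns are excluded from the prevalence test (but retained in the
    output).  The gate is strict: exactly min_fraction is dropped.
    """
    groups = _group_cols(roles, table.columns, include_qc=False)
    keep = pd.Series(False, index=table.index)
    for cols in groups.values():
        frac = (table[cols] > 0).sum(axis=1) / len(cols)
        keep |= frac > min_fraction
    return table.loc[keep]


def normalize_total_intensity(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to the median column sum."""
    sums = table.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise DataError(f"zero total intensity in columns: {bad}")
    return table * (float(sums.median()) / sums)


def pareto_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite Pareto scaling: (x - mean) / sqrt(sd), sample sd.

    Constant metabolites scale to all zeros (with a warning).
    """
    mean = table.mean(axis=1)
    sd = table.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant metabolite(s) scaled to zeros",
                      stacklevel=2)
    denom = np.sqrt(sd.where(~zero, 1.0))
    scaled = table.sub(mean, axis=0).div(denom, axis=0)
    scaled.loc[zero] = 0.0
    return scaled


def pca_scores(scaled: pd.DataFrame, k: int,
               ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Leading principal components of the samples.

    ``scaled`` is metabolites x samples (already centred by Pareto scaling).
    Returns (scores: samples x k, loadings: metabolites x k, variance
    fractions).  Sign convention: the largest-|loading| element of each
    component is positive.  k beyond the matrix rank is reduced with a
    warning.
    """
    X = scaled.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s.max() * 1e-12)) if s.size else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; reduced", stacklevel=2)
        k = rank
    tot = float((s ** 2).sum())
    var_frac = (s[:k] ** 2) / tot if tot > 0 else np.zeros(k)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for a in range(k):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    comp = [f"PC{a + 1}" for a in range(k)]
    return (pd.DataFrame(scores, index=scaled.columns, columns=comp),
            pd.DataFrame(loadings, index=scaled.index, columns=comp),
            var_frac)


def qc_tightness(scores: pd.DataFrame, roles: dict[str, str],
                 ) -> dict[str, float]:
    """Mean within-QC pairwise distance vs mean between-group distance.

    Small QC distances relative to group separation indicate stable
    acquisition, the property QC pooling is meant to demonstrate.
    """
    qc = [c for c in scores.index if roles.get(c) == QC_ROLE]
    groups = _group_cols(roles, list(scores.index), include_qc=False)
    if len(qc) < 2 or len(groups) != 2:
        raise DataError("need >= 2 QC samples and exactly two groups")
    (ga, ca), (gb, cb) = groups.items()
    qs = scores.loc[qc].to_numpy()
    d_qc = np.mean([np.linalg.norm(qs[i] - qs[j])
                    for i in range(len(qs)) for j in range(i + 1, len(qs))])
    a, b = scores.loc[ca].to_numpy(), scores.loc[cb].to_numpy()
    d_between = np.mean([np.linalg.norm(x - y) for x in a for y in b])
    return {"qc_mean_distance": float(d_qc),
            "between_group_mean_distance": float(d_between)}


def plsda_vip(scaled: pd.DataFrame, roles: dict[str, str],
              n_components: int = 2,
              group_pair: Optional[tuple[str, str]] = None) -> VipScores:
    """PLS-DA (NIPALS, one binary response) with VIP scores.

    VIP_j = sqrt(p * sum_a SSY_a * (w_aj / ||w_a||)^2 / sum_a SSY_a) where
    SSY_a is the response variance explained by component a.  QC columns
    are excluded from the fit.  mean(VIP^2) = 1 holds by construction and
    is re-asserted numerically.
    """
    if n_components < 1:
        raise ConfigError("n_components must be >= 1")
    groups = _group_cols(roles, scaled.columns, include_qc=False)
    if group_pair is None:
        if len(groups) != 2:
            raise DataError(f"need exactly two groups, found {sorted(groups)}")
        group_pair = tuple(groups)  # type: ignore[assignment]
    g_a, g_b = group_pair
    for g in group_pair:
        if len(groups.get(g, [])) < 2:
            raise ConfigError(f"group '{g}' needs >= 2 samples")
    cols = groups[g_a] + groups[g_b]
    X = scaled[cols].to_numpy(dtype=float).T  # samples x features
    y = np.array([1.0 if roles[c] == g_a else 0.0 for c in cols])
    X = X - X.mean(axis=0)
    y = y - y.mean()
    n_samp, p = X.shape
    A = min(n_components, n_samp - 1, p)
    W, ssy = [], []
    Xa, ya = X.copy(), y.copy()
    for _ in range(A):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pl = Xa.T @ t / tt
        q = float(ya @ t) / tt
        W.append(w)
        ssy.append(q * q * tt)  # response sum of squares explained
        Xa = Xa - np.outer(t, pl)
        ya = ya - q * t
    if not W:
        raise DataError("PLS fit degenerate: no usable component")
    Wm = np.stack(W)               # A x p, rows unit-norm
    ssy_arr = np.array(ssy)
    vip = np.sqrt(p * (ssy_arr[:, None] * Wm ** 2).sum(axis=0) / ssy_arr.sum())
    scores = pd.Series(vip, index=scaled.index, name="VIP")
    mean_sq = float((scores ** 2).mean())
    if abs(mean_sq - 1.0) > 1e-6:
        raise AssertionError(f"VIP normalisation violated: mean(VIP^2)={mean_sq}")
    return VipScores(scores, len(W))


def group_ttest_table(table: pd.DataFrame, roles: dict[str, str],
                      group_pair: Optional[tuple[str, str]] = None,
                      log2: bool = True) -> pd.DataFrame:
    """Two-sided t-test per metabolite on (log2) intensities, QC excluded."""
    groups = _group_cols(roles, table.columns, include_qc=False)
    if group_pair is None:
        if len(groups) != 2:
            raise DataError(f"need exactly two groups, found {sorted(groups)}")
        group_pair = tuple(groups)  # type: ignore[assignment]
    g_a, g_b = group_pair
    a = table[groups[g_a]].to_numpy(dtype=float)
    b = table[groups[g_b]].to_numpy(dtype=float)
    if log2:
        floor = np.nextafter(0, 1)
        a, b = np.log2(np.maximum(a, floor)), np.log2(np.maximum(b, floor))
    with warnings.catch_warnings():
        # near-constant rows trip scipy's precision-loss warning; such rows
        # get p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = table[groups[g_a]].mean(axis=1) / table[groups[g_b]].mean(axis=1)
    return pd.DataFrame({"fold": fold, "t_stat": res.statistic, "p_value": p},
                        index=table.index)


def screen_metabolites(vip: VipScores, stats_table: pd.DataFrame,
                       vip_cutoff: float = 1.0,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Sequential gate: VIP first, then the t-test on the VIP-passing subset.

    Returns the significant metabolites sorted by ascending p, with their
    VIP, fold and p values.
    """
    passing = vip.scores.index[vip.scores > vip_cutoff]
    sub = stats_table.loc[[i for i in passing if i in stats_table.index]].copy()
    sub["VIP"] = vip.scores.loc[sub.index]
    sig = sub[sub["p_value"] < alpha]
    return sig.sort_values("p_value", kind="mergesort")


def permuted_roles(roles: dict[str, str], rng: np.random.Generator,
                   ) -> dict[str, str]:
    """Group labels permuted among non-QC samples (null-calibration helper)."""
    cols = [c for c, r in roles.items() if r != QC_ROLE]
    labels = [roles[c] for c in cols]
    rng.shuffle(labels)
    out = dict(roles)
    out.update(dict(zip(cols, labels)))
    return out
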