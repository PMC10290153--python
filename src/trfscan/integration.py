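"""Differential proteins, target/DEP overlap, and over-representation.

DEPs are called with the conventional TMT screen: fold change of the
linear-scale group means gated at >1.20 (up) or <0.83 (down) together with a
two-sided t-test on log2 abundances at p < 0.05.  Predicted fragment targets
are intersected with the down-regulated DEP set; the overlap is reported as
a percentage of the down set with a hypergeometric upper-tail enrichment p.
Over-representation against user-supplied gene sets uses the one-sided
hypergeometric test (the one-tailed Fisher exact test) with
Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError


@dataclass
class DepCutoffs:
    """Differential-protein gates (fold on linear means, p on log2 t-test)."""

    up_fold: float = 1.20
    down_fold: float = 0.83
    alpha: float = 0.05

    def validate(self) -> "DepCutoffs":
        if not self.down_fold < 1 < self.up_fold:
            raise ConfigError("require down_fold < 1 < up_fold")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        return self


@dataclass
class OverlapResult:
    n_targets: int
    n_down_deps: int
    n_overlap: int
    pct_of_down: float    # 100 * n_overlap / n_down_deps
    hypergeom_p: float
    universe_size: int


def call_deps(table: pd.DataFrame, groups: dict[str, str],
              group_pair: Optional[tuple[str, str]] = None,
              cutoffs: DepCutoffs = DepCutoffs(),
              ) -> tuple[set[str], set[str], pd.DataFrame]:
    """Call up/down differential proteins between two groups.

    ``table`` holds linear-scale abundances (proteins x samples).  Fold is
    mean(first)/mean(second) on the linear scale; the test is a two-sided
    t-test on log2 values.  Returns (up set, down set, per-protein stats).
    """
    cutoffs.validate()
    if (table.values <= 0).any():
        raise DataError("non-positive abundance: cannot log-transform")
    if group_pair is None:
        seen: list[str] = []
        for col in table.columns:
            g = groups[col]
            if g not in seen:
                seen.append(g)
        if len(seen) != 2:
            raise DataError(f"need exactly two groups, found {seen}")
        group_pair = (seen[0], seen[1])
    g_a, g_b = group_pair
    cols_a = [c for c in table.columns if groups.get(c) == g_a]
    cols_b = [c for c in table.columns if groups.get(c) == g_b]
    for g, cols in ((g_a, cols_a), (g_b, cols_b)):
        if len(cols) < 2:
            raise ConfigError(f"group '{g}' has {len(cols)} samples; need >= 2")
    a = table[cols_a].to_numpy(dtype=float)
    b = table[cols_b].to_numpy(dtype=float)
    fold = a.mean(axis=1) / b.mean(axis=1)
    res = stats.ttest_ind(np.log2(a), np.log2(b), axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance equal rows
    statsdf = pd.DataFrame({"fold": fold, "t_stat": res.statistic, "p_value": p},
                           index=table.index)
    up = set(statsdf.index[(fold > cutoffs.up_fold) & (p < cutoffs.alpha)])
    down = set(statsdf.index[(fold < cutoffs.down_fold) & (p < cutoffs.alpha)])
    return up, down, statsdf


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_targets_deps(target_genes: Iterable[str],
                         down_deps: Iterable[str],
                         universe: Iterable[str]) -> OverlapResult:
    """Intersect predicted targets with down-regulated DEPs.

    Both sets must lie inside the declared universe.  Reports the overlap
    count, its percentage of the down-DEP set, and the hypergeometric
    upper-tail p of seeing at least that many targets among the down DEPs.
    """
    universe = set(universe)
    targets = set(target_genes)
    down = set(down_deps)
    for name, s in (("target", targets), ("down-DEP", down)):
        stray = s - universe
        if stray:
            raise DataError(
                f"{name} genes outside the universe: {sorted(stray)[:10]}")
    overlap = targets & down
    k = len(overlap)
    pct = 100.0 * k / len(down) if down else 0.0
    p = hypergeom_upper_tail(k, len(universe), len(targets), len(down))
    return OverlapResult(len(targets), len(down), k, pct, p, len(universe))


def ora(query_genes: Iterable[str],
        gene_sets: dict[str, set[str]],
        universe: Iterable[str]) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    One-sided hypergeometric p per set (equivalent to the one-tailed Fisher
    exact test), BH-adjusted q across sets.  Output sorted by p, ties by
    set id.  Gene-set members outside the universe are ignored.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    query = set(query_genes) & universe
    N, n = len(universe), len(query)
    rows = []
    for set_id in sorted(gene_sets):
        members = gene_sets[set_id] & universe
        K = len(members)
        k = len(query & members)
        rows.append({"set_id": set_id, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_upper_tail(k, N, K, n)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (set_id, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(sets):
            members = "\t".join(sorted(sets[set_id]))
            fh.write(f"{set_id}\tsynthetic\t{members}\n")
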