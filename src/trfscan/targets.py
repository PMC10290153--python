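"""Complementarity-based target prediction for a small RNA against 3'UTRs.

The scan follows the miRanda conventions: Smith-Waterman-style local
alignment of the small RNA (5'->3') against the reverse of a UTR window,
scoring Watson-Crick complements as matches, G:U wobbles at a reduced
reward, affine gap penalties, and a position-dependent multiplier on the
small-RNA seed region (positions 2-8 from the 5' end).  Thermodynamic
duplex energies are replaced by a paired-fraction x GC-weight stability
proxy with its own threshold.

Windows of width (fragment length + extension) slide along each UTR;
surviving hits above the score and stability thresholds are merged when
they overlap, keeping the best score.  A gene is called a target when any
merged hit survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
# complementary pairs (query base, target base) both read on their own strand
_MATCH_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1)}
_WOBBLE_PAIRS = {(2, 3), (3, 2)}  # G:U / U:G

MIN_QUERY, MAX_QUERY = 16, 40
MAX_WINDOW = 80


@dataclass
class DuplexParams:
    """Scoring scheme of the duplex alignment (miRanda-convention defaults)."""

    match: float = 5.0
    gu_wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0
    seed_start: int = 2   # 1-based, from the small-RNA 5' end
    seed_end: int = 8
    score_threshold: float = 140.0
    # calibrated on a dinucleotide-shuffle null: random-complementarity hits
    # above the score threshold plateau near 0.55; end-to-end sites pair at
    # ~0.75 (see docs/methods.md)
    stability_threshold: float = 0.6
    window_extension: int = 15
    window_step: int = 5

    def validate(self) -> "DuplexParams":
        if not self.gap_open <= self.gap_extend <= 0:
            raise DataError("require gap_open <= gap_extend <= 0")
        if self.seed_scale < 1:
            raise DataError("seed_scale must be >= 1")
        return self

    def submatrix(self) -> np.ndarray:
        """5x5 pair-score matrix indexed by encoded (query, target) base."""
        sub = np.full((5, 5), self.mismatch)
        for q, t in _MATCH_PAIRS:
            sub[q, t] = self.match
        for q, t in _WOBBLE_PAIRS:
            sub[q, t] = self.gu_wobble
        sub[4, :] = self.mismatch
        sub[:, 4] = self.mismatch
        return sub

    def seed_scales(self, m: int) -> np.ndarray:
        scale = np.ones(m)
        lo = max(self.seed_start - 1, 0)
        scale[lo: self.seed_end] = self.seed_scale
        return scale


@dataclass
class DuplexAlignment:
    """Best local duplex alignment of a small RNA against one window."""

    score: float
    q_start: int = 0   # 1-based on the small RNA, closed
    q_end: int = 0
    t_start: int = 0   # 1-based on the window in original orientation, closed
    t_end: int = 0
    n_gaps: int = 0
    paired_fraction: float = 0.0
    gc_fraction: float = 0.0
    query_row: str = ""
    pair_row: str = ""
    target_row: str = ""

    @property
    def stability(self) -> float:
        """Paired-fraction x GC-weight proxy for duplex stability."""
        return self.paired_fraction * (0.5 + 0.5 * self.gc_fraction)


@dataclass
class TargetHit:
    """A surviving complementarity site on a UTR (1-based closed coords)."""

    utr_id: str
    start: int
    end: int
    score: float
    stability: float
    alignment: DuplexAlignment = field(repr=False, default=None)  # type: ignore


def _encode(seq: str, what: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise DataError(f"{what}: invalid base {exc.args[0]!r}") from exc


def align_duplex(small_rna: str, utr_window: str,
                 params: DuplexParams = DuplexParams()) -> DuplexAlignment:
    """Best local alignment of the small RNA against the reversed window.

    Affine-gap Smith-Waterman with complementarity scoring; gaps are always
    flanked by paired columns (an alignment starts and ends in a pairing).
    Deterministic tie-break: highest score, then fewer gaps, then the
    smaller UTR start.  U is accepted and treated as T.
    """
    params.validate()
    if not MIN_QUERY <= len(small_rna) <= MAX_QUERY:
        raise DataError(
            f"small RNA length {len(small_rna)} outside [{MIN_QUERY}, {MAX_QUERY}]")
    if len(utr_window) > MAX_WINDOW:
        raise DataError(f"window length {len(utr_window)} exceeds {MAX_WINDOW}")
    q = _encode(small_rna, "small RNA")
    t = _encode(utr_window, "UTR window")[::-1]  # reversed: antiparallel pairing
    m, n = len(q), len(t)
    sub = params.submatrix()
    scale = params.seed_scales(m)
    go, ge = params.gap_open, params.gap_extend
    NEG = -1e18

    M = np.zeros((m + 1, n + 1))
    Ix = np.full((m + 1, n + 1), NEG)  # gap in target (consumes query)
    Iy = np.full((m + 1, n + 1), NEG)  # gap in query (consumes target)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 new, 1 diagM, 2 diagIx, 3 diagIy
    for i in range(1, m + 1):
        s_i = sub[q[i - 1]] * scale[i - 1]
        for j in range(1, n + 1):
            s = s_i[t[j - 1]]
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            best_prev = max(prev)
            if best_prev <= 0:
                M[i, j] = max(0.0, s)
                ptr[i, j] = 0
            else:
                M[i, j] = max(0.0, best_prev + s)
                # tie-break: prefer the match state (fewer gaps)
                ptr[i, j] = 1 + int(np.argmax(prev)) if M[i, j] > 0 else 0
            Ix[i, j] = max(M[i - 1, j] + go, Ix[i - 1, j] + ge)
            Iy[i, j] = max(M[i, j - 1] + go, Iy[i, j - 1] + ge)

    best = float(M.max())
    if best <= 0:
        return DuplexAlignment(score=0.0)
    # among equal best cells take the largest j (smallest UTR start), then largest i
    cells = np.argwhere(M == best)
    i_best, j_best = max(cells, key=lambda c: (c[1], c[0]))
    return _traceback(q, t, M, Ix, Iy, int(i_best), int(j_best), params,
                      small_rna, utr_window)


def _traceback(q, t, M, Ix, Iy, i, j, params, small_rna, window_str,
               ) -> DuplexAlignment:
    sub = params.submatrix()
    scale = params.seed_scales(len(q))
    go, ge = params.gap_open, params.gap_extend
    rev = window_str[::-1].upper().replace("U", "T")
    qs = small_rna.upper().replace("U", "T")
    cols: list[tuple[str, str, str]] = []
    n_gaps = paired = gc = 0
    score = float(M[i, j])
    i_end, j_end = i, j
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] <= 0:
                break
            s = sub[q[i - 1], t[j - 1]] * scale[i - 1]
            pair = (int(q[i - 1]), int(t[j - 1]))
            if pair in _MATCH_PAIRS:
                mark, paired = "|", paired + 1
                if pair in {(1, 2), (2, 1)}:
                    gc += 1
            elif pair in _WOBBLE_PAIRS:
                mark, paired = ":", paired + 1
            else:
                mark = " "
            cols.append((qs[i - 1], mark, rev[j - 1]))
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            if prev <= 0 or (i == 0 or j == 0):
                break
            # prefer M (fewer gaps), then Ix, then Iy
            if abs(M[i, j] - prev) < 1e-9:
                state = "M"
            elif abs(Ix[i, j] - prev) < 1e-9:
                state = "Ix"
            elif abs(Iy[i, j] - prev) < 1e-9:
                state = "Iy"
            else:  # numeric fallback
                state = "M"
        elif state == "Ix":  # gap in target, consumes query base
            cols.append((qs[i - 1], " ", "-"))
            n_gaps += 1
            if abs(Ix[i, j] - (M[i - 1, j] + go)) < 1e-9:
                state = "M"
            i -= 1
        else:  # Iy: gap in query, consumes target base
            cols.append(("-", " ", rev[j - 1]))
            n_gaps += 1
            if abs(Iy[i, j] - (M[i, j - 1] + go)) < 1e-9:
                state = "M"
            j -= 1
    i_start, j_start = i + 1, j + 1
    cols.reverse()
    ncols = len(cols)
    n = len(t)
    return DuplexAlignment(
        score=score,
        q_start=i_start, q_end=i_end,
        t_start=n - j_end + 1, t_end=n - j_start + 1,
        n_gaps=n_gaps,
        paired_fraction=paired / ncols if ncols else 0.0,
        gc_fraction=gc / paired if paired else 0.0,
        query_row="".join(c[0] for c in cols),
        pair_row="".join(c[1] for c in cols),
        target_row="".join(c[2] for c in cols),
    )


def _score_windows(qcodes: np.ndarray, wincodes: np.ndarray,
                   params: DuplexParams) -> np.ndarray:
    """Vectorised best local duplex score for a batch of reversed windows.

    ``wincodes``: (n_windows, width) encoded, already reversed.  Same
    recurrence as :func:`align_duplex`, batched across windows.
    """
    n_win, width = wincodes.shape
    m = len(qcodes)
    sub = params.submatrix()
    scale = params.seed_scales(m)
    go, ge = params.gap_open, params.gap_extend
    NEG = -1e18
    M_prev = np.zeros((n_win, width))
    Ix_prev = np.full((n_win, width), NEG)
    Iy_prev = np.full((n_win, width), NEG)
    best = np.zeros(n_win)
    j_idx = np.arange(width)
    for i in range(m):
        s_row = sub[qcodes[i]][wincodes] * scale[i]
        H = np.maximum(M_prev, np.maximum(Ix_prev, Iy_prev))
        H_shift = np.empty_like(H)
        H_shift[:, 0] = 0.0
        H_shift[:, 1:] = np.maximum(H[:, :-1], 0.0)
        M_cur = np.maximum(0.0, H_shift + s_row)
        Ix_cur = np.maximum(M_prev + go, Ix_prev + ge)
        # gap in query: Iy[j] = j*ge + cummax_{k<j}(M[k] + go - (k+1)*ge)
        B = M_cur + go - (j_idx + 1) * ge
        cm = np.maximum.accumulate(B, axis=1)
        Iy_cur = np.full((n_win, width), NEG)
        Iy_cur[:, 1:] = cm[:, :-1] + j_idx[1:] * ge
        np.maximum(best, M_cur.max(axis=1), out=best)
        M_prev, Ix_prev, Iy_prev = M_cur, Ix_cur, Iy_cur
    return best


def scan_targets(fragment: str, utrs: dict[str, str],
                 params: DuplexParams = DuplexParams(),
                 ) -> dict[str, list[TargetHit]]:
    """Sliding-window duplex scan of the fragment against every UTR.

    Windows of width len(fragment) + window_extension advance by
    window_step (plus one end-anchored window); windows above both the
    score and stability thresholds are realigned for full detail, mapped to
    UTR coordinates, and overlapping hits are merged keeping the maximum
    score.  Returns {utr_id: merged hits}; UTRs without hits map to [].
    """
    params.validate()
    if not utrs:
        raise DataError("UTR set is empty")
    qcodes = _encode(fragment, "fragment")
    width = len(fragment) + params.window_extension
    out: dict[str, list[TargetHit]] = {}
    for utr_id, seq in utrs.items():
        L = len(seq)
        if L < len(fragment):
            out[utr_id] = []
            continue
        w = min(width, L)
        starts = sorted({*range(0, L - w + 1, params.window_step), L - w})
        codes = _encode(seq, f"UTR {utr_id}")
        wincodes = np.stack([codes[s: s + w][::-1] for s in starts])
        scores = _score_windows(qcodes, wincodes, params)
        hits: list[TargetHit] = []
        for s0, sc in zip(starts, scores):
            if sc < params.score_threshold:
                continue
            aln = align_duplex(fragment, seq[s0: s0 + w], params)
            if aln.score < params.score_threshold:
                continue
            if aln.stability < params.stability_threshold:
                continue
            hits.append(TargetHit(
                utr_id=utr_id,
                start=s0 + aln.t_start,
                end=s0 + aln.t_end,
                score=aln.score,
                stability=aln.stability,
                alignment=aln,
            ))
        out[utr_id] = _merge_hits(hits)
    return out


def _merge_hits(hits: list[TargetHit]) -> list[TargetHit]:
    """Collapse overlapping hits, keeping the best score per overlap cluster.

    Ties break toward the smaller UTR start.
    """
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    merged: list[TargetHit] = []
    cluster: list[TargetHit] = []
    cluster_end = -1
    for h in hits + [None]:  # type: ignore[list-item]
        if h is not None and (not cluster or h.start <= cluster_end):
            cluster.append(h)
            cluster_end = max(cluster_end, h.end)
            continue
        if cluster:
            merged.append(max(cluster, key=lambda c: (c.score, -c.start)))
        if h is not None:
            cluster, cluster_end = [h], h.end
    return merged


def predicted_genes(hits_by_utr: dict[str, list[TargetHit]]) -> set[str]:
    """Gene-level calls: any surviving merged hit."""
    return {utr_id for utr_id, hits in hits_by_utr.items() if hits}
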