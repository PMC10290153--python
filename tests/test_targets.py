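"""Duplex alignment against a brute-force DP oracle; window scan behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trfscan.errors import DataError
from trfscan.sequtils import dinucleotide_shuffle, revcomp
from trfscan.targets import (DuplexParams, _score_windows, _encode,
                             align_duplex, predicted_genes, scan_targets)

BASES = "ACGT"
COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
MATCH_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


def brute_force_score(query: str, window: str, params: DuplexParams) -> float:
    """Plain O(n^2 m) local-alignment oracle without affine optimisation.

    Alignments start and end in a paired column; a gap of length k costs
    gap_open + (k-1) * gap_extend and is enumerated explicitly.
    """
    q = query.upper().replace("U", "T")
    t = window.upper().replace("U", "T")[::-1]
    m, n = len(q), len(t)
    scale = [params.seed_scale if params.seed_start <= i + 1 <= params.seed_end
             else 1.0 for i in range(m)]

    def pair_score(i, j):
        pr = (q[i], t[j])
        if pr in MATCH_PAIRS:
            s = params.match
        elif pr in WOBBLE_PAIRS:
            s = params.gu_wobble
        else:
            s = params.mismatch
        return s * scale[i]

    NEG = float("-inf")
    M = [[NEG] * n for _ in range(m)]
    best = 0.0
    for i in range(m):
        for j in range(n):
            s = pair_score(i, j)
            cand = s  # fresh start
            if i > 0 and j > 0:
                if M[i - 1][j - 1] > 0:
                    cand = max(cand, M[i - 1][j - 1] + s)
                for k in range(1, i):  # gap in target: skip query i-k..i-1
                    prev = M[i - 1 - k][j - 1]
                    if prev > 0:
                        cand = max(cand, prev + params.gap_open
                                   + (k - 1) * params.gap_extend + s)
                for k in range(1, j):  # gap in query: skip target chars
                    prev = M[i - 1][j - 1 - k]
                    if prev > 0:
                        cand = max(cand, prev + params.gap_open
                                   + (k - 1) * params.gap_extend + s)
            M[i][j] = cand
            best = max(best, cand)
    return best


def _random_seq(rng, n):
    return "".join(rng.choice(list(BASES), n))


class TestAlignDuplex:
    def test_perfect_pairing_closed_form(self):
        """Gap-free perfect complement: 13 plain + 7 seed-scaled matches."""
        rng = np.random.default_rng(1)
        q = _random_seq(rng, 20)
        aln = align_duplex(q, revcomp(q))
        assert aln.score == pytest.approx(5 * 13 + 5 * 4.0 * 7)
        assert aln.n_gaps == 0
        assert aln.paired_fraction == 1.0
        assert (aln.q_start, aln.q_end) == (1, 20)

    def test_no_complementarity_scores_zero(self):
        aln = align_duplex("A" * 20, "A" * 20)  # A cannot pair with A
        assert aln.score == 0.0

    def test_u_accepted_as_t(self):
        rng = np.random.default_rng(2)
        q = _random_seq(rng, 18)
        assert align_duplex(q.replace("T", "U"), revcomp(q)).score == \
            align_duplex(q, revcomp(q)).score

    def test_alphabet_violation_rejected(self):
        with pytest.raises(DataError):
            align_duplex("ACGTACGTACGTACGTX", "ACGT")

    def test_length_guards(self):
        with pytest.raises(DataError):
            align_duplex("ACGT", "ACGTACGT")
        with pytest.raises(DataError):
            align_duplex("A" * 20, "C" * 100)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = DuplexParams()
        q = _random_seq(rng, int(rng.integers(16, 21)))
        t = _random_seq(rng, int(rng.integers(16, 41)))
        assert align_duplex(q, t, params).score == \
            pytest.approx(brute_force_score(q, t, params))

    @pytest.mark.parametrize("seed", range(10))
    def test_batched_scorer_matches_full_alignment(self, seed):
        rng = np.random.default_rng(100 + seed)
        q = _random_seq(rng, 20)
        windows = [_random_seq(rng, 35) for _ in range(8)]
        wincodes = np.stack([_encode(w, "w")[::-1] for w in windows])
        batched = _score_windows(_encode(q, "q"), wincodes, DuplexParams())
        for w, s in zip(windows, batched):
            assert align_duplex(q, w).score == pytest.approx(s)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_score_invariant_under_double_revcomp(self, seed):
        """Reverse-complementing both strands maps Watson-Crick pairs to
        Watson-Crick pairs, so with position-independent scoring and wobble
        scored as mismatch (G:U is not closed under complementation) the
        best local score is unchanged."""
        rng = np.random.default_rng(seed)
        params = DuplexParams(seed_scale=1.0, gu_wobble=-3.0)
        q = _random_seq(rng, 18)
        t = _random_seq(rng, 30)
        assert align_duplex(q, t, params).score == \
            pytest.approx(align_duplex(revcomp(q), revcomp(t), params).score)


class TestScanTargets:
    def _embed(self, rng, site, length=300):
        s = _random_seq(rng, length)
        p = int(rng.integers(0, length - len(site)))
        return s[:p] + site + s[p + len(site):], p

    def test_embedded_perfect_site_single_merged_hit(self):
        rng = np.random.default_rng(5)
        frag = _random_seq(rng, 32)
        utr, pos = self._embed(rng, revcomp(frag))
        hits = scan_targets(frag, {"u": utr})["u"]
        assert len(hits) == 1
        assert hits[0].start <= pos + 1 and hits[0].end >= pos + 32
        assert hits[0].score == pytest.approx(5 * 25 + 5 * 4.0 * 7)

    def test_two_distant_sites_two_hits(self):
        rng = np.random.default_rng(6)
        frag = _random_seq(rng, 32)
        site = revcomp(frag)
        filler = _random_seq(rng, 120)
        utr = site + filler + site
        hits = scan_targets(frag, {"u": utr})["u"]
        assert len(hits) == 2

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        frag = _random_seq(rng, 32)
        utrs = {f"u{i}": _random_seq(rng, 200) for i in range(20)}
        utrs["planted"], _ = self._embed(rng, revcomp(frag), 200)
        lo = predicted_genes(scan_targets(frag, utrs,
                                          DuplexParams(score_threshold=100)))
        hi = predicted_genes(scan_targets(frag, utrs,
                                          DuplexParams(score_threshold=200)))
        assert hi <= lo
        assert "planted" in hi

    def test_shuffle_null_rate_supports_thresholds(self):
        """Dinucleotide-preserving shuffles of target-bearing UTRs destroy
        the site: the null gene-level call rate stays low while every intact
        site is recovered under the same thresholds."""
        rng = np.random.default_rng(8)
        py_rng = np.random.default_rng(9)
        frag = _random_seq(rng, 32)
        intact, shuffled = {}, {}
        for i in range(100):
            utr, _ = self._embed(rng, revcomp(frag))
            intact[f"u{i}"] = utr
            shuffled[f"s{i}"] = dinucleotide_shuffle(utr, py_rng)
        null_rate = len(predicted_genes(scan_targets(frag, shuffled))) / 100
        planted_rate = len(predicted_genes(scan_targets(frag, intact))) / 100
        assert planted_rate == 1.0
        assert null_rate <= 0.15

    def test_empty_utr_set_rejected(self):
        with pytest.raises(DataError):
            scan_targets("A" * 20, {})


def test_dinucleotide_shuffle_preserves_composition():
    rng = np.random.default_rng(10)
    seq = _random_seq(rng, 200)
    shuf = dinucleotide_shuffle(seq, rng)
    def dinucs(s):
        from collections import Counter
        return Counter(s[i:i + 2] for i in range(len(s) - 1))
    assert dinucs(seq) == dinucs(shuf)
    assert shuf != seq
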