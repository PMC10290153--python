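"""Tiny nucleotide-string helpers shared across modules."""

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Altschul-Erikson style: permute the outgoing-edge lists of the
    character digraph, retrying until the implied walk uses every edge
    (valid Eulerian path from the first to the last character).
    """
    if len(seq) < 3:
        return seq
    for _ in range(1000):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for targets in edges.values():
            rng.shuffle(targets)
        out = [seq[0]]
        cur = seq[0]
        ok = True
        for _step in range(len(seq) - 1):
            nexts = edges.get(cur)
            if not nexts:
                ok = False
                break
            cur = nexts.pop()
            out.append(cur)
        if ok and not any(edges[k] for k in edges):
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")
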