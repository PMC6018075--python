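"""Independent brute-force oracles used by the test suite.

These deliberately reimplement, by the most naive route available, the
quantities the package computes efficiently: sliding-window substring
counts, exhaustive global-alignment enumeration, and grouped spot sums.
"""

from __future__ import annotations


def naive_count(sequence: str, motif: str, mode: str = "overlapping") -> list[int]:
    """Sliding-window occurrence starts; greedy left-consumption if non-overlapping."""
    positions = []
    i = 0
    while i <= len(sequence) - len(motif):
        if sequence[i : i + len(motif)] == motif:
            positions.append(i)
            i += 1 if mode == "overlapping" else len(motif)
        else:
            i += 1
    return positions


def enumerate_alignment(a: str, b: str, match=1, mismatch=0, gap=-1):
    """Exhaustively enumerate every global alignment of a and b.

    Returns (score, matches, length) of the alignment maximising
    (score, matches, -length) lexicographically.
    """
    best = None

    def rec(i, j, score, matches, length):
        nonlocal best
        if i == len(a) and j == len(b):
            key = (score, matches, -length)
            if best is None or key > best:
                best = key
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            rec(i + 1, j + 1, score + (match if hit else mismatch),
                matches + (1 if hit else 0), length + 1)
        if i < len(a):
            rec(i + 1, j, score + gap, matches, length + 1)
        if j < len(b):
            rec(i, j + 1, score + gap, matches, length + 1)

    rec(0, 0, 0, 0, 0)
    score, matches, neg_length = best
    return score, matches, -neg_length


def group_sums(records) -> dict[str, tuple[int, float]]:
    """Brute-force group-and-sum of spot records by category."""
    out: dict[str, tuple[int, float]] = {}
    for rec in records:
        n, v = out.get(rec.category, (0, 0.0))
        out[rec.category] = (n + 1, v + rec.volume_norm)
    return out
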