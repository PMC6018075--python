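"""Global pairwise alignment by dynamic programming.

Identity-based scoring (match +1, mismatch 0, linear gap penalty by
default), with a deterministic lexicographic tie-break among co-optimal
alignments: maximise score, then matches, then minimise alignment length.
The tie-break makes percent identity a well-defined function of the two
sequences rather than of an arbitrary traceback choice.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["global_alignment_stats", "pairwise_identity"]


@njit(cache=True)
def _nw(a, b, match, mismatch, gap):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    S = np.empty((n + 1, m + 1), np.int64)  # score
    M = np.empty((n + 1, m + 1), np.int64)  # matches on the best path
    L = np.empty((n + 1, m + 1), np.int64)  # alignment length on the best path
    S[0, 0] = 0
    M[0, 0] = 0
    L[0, 0] = 0
    for j in range(1, m + 1):
        S[0, j] = j * gap
        M[0, j] = 0
        L[0, j] = j
    for i in range(1, n + 1):
        S[i, 0] = i * gap
        M[i, 0] = 0
        L[i, 0] = i
        for j in range(1, m + 1):
            hit = a[i - 1] == b[j - 1]
            ds = S[i - 1, j - 1] + (match if hit else mismatch)
            dm = M[i - 1, j - 1] + (1 if hit else 0)
            dl = L[i - 1, j - 1] + 1
            us = S[i - 1, j] + gap
            um = M[i - 1, j]
            ul = L[i - 1, j] + 1
            ls = S[i, j - 1] + gap
            lm = M[i, j - 1]
            ll = L[i, j - 1] + 1
            # lexicographic max over (score, matches, -length)
            bs, bm, bl = ds, dm, dl
            if (us > bs) or (us == bs and (um > bm or (um == bm and ul < bl))):
                bs, bm, bl = us, um, ul
            if (ls > bs) or (ls == bs and (lm > bm or (lm == bm and ll < bl))):
                bs, bm, bl = ls, lm, ll
            S[i, j] = bs
            M[i, j] = bm
            L[i, j] = bl
    return S[n, m], M[n, m], L[n, m]


def _encode(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).astype(np.int64)


def global_alignment_stats(
    seq_a: str, seq_b: str, match: int = 1, mismatch: int = 0, gap: int = -1
) -> tuple[int, int, int]:
    """(score, matches, alignment_length) of the optimal global alignment."""
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    score, matches, length = _nw(_encode(seq_a), _encode(seq_b), match, mismatch, gap)
    return int(score), int(matches), int(length)


def pairwise_identity(
    seq_a: str, seq_b: str, match: int = 1, mismatch: int = 0, gap: int = -1
) -> float:
    """Percent identity of the optimal global alignment.

    identity = matches / alignment_length * 100.  Symmetric, and equal to
    100 iff the sequences are identical (under the default parameters).
    """
    _, matches, length = global_alignment_stats(seq_a, seq_b, match, mismatch, gap)
    return 100.0 * matches / length
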