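"""Independent brute-force oracles used only by the test suite.

Each oracle is a deliberately simple, slow re-derivation of a quantity
the package computes by a different route.
"""

from __future__ import annotations

from math import comb


def gotoh_local_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Textbook affine-gap Smith-Waterman score (BLAST gap semantics: a gap
    of length L costs |gap_open| + L * |gap_extend|)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    open_cost = gap_open + gap_extend  # first gap position
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]  # ends in aligned pair
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in gap in a (b consumed)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_cost, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + open_cost, Y[i][j - 1] + gap_extend)
            best = max(best, M[i][j])
    return best


def fisher_two_tailed_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration of all tables with
    the observed margins."""
    n = a + b + c + d
    r, s = a + b, a + c
    denom = comb(n, r)

    def pmf(k: int):
        return comb(s, k) * comb(n - s, r - k) / denom

    lo, hi = max(0, r + s - n), min(r, s)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-12))


def naive_sliding_gc(seq: str, window: int, step: int) -> list[float]:
    """Per-window GC fraction by recounting every window from scratch."""
    out = []
    for start in range(0, len(seq) - window + 1, step):
        w = seq[start : start + window].upper()
        gc = sum(1 for ch in w if ch in "GC")
        at = sum(1 for ch in w if ch in "AT")
        out.append(gc / (gc + at) if gc + at else float("nan"))
    return out
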