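"""Independent brute-force oracles used to pin expected values.

These deliberately share no code with the package: the aligner oracle is a
plain three-matrix affine dynamic program, the Fisher oracle a direct
hypergeometric tail sum over binomial coefficients, and the Holm oracle the
textbook step-down procedure.
"""

from __future__ import annotations

from math import comb

NEG_INF = float("-inf")


def sw_affine_score(
    q: str,
    s: str,
    match: float = 1.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Optimal Smith–Waterman score; a gap of length g costs
    gap_open + g * gap_extend."""
    n, m = len(q), len(s)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + first, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + first, F[i - 1][j] + gap_extend)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(population n+N, successes k+K, draws n) —
    the one-sided Fisher p for the 2x2 table (k, n-k; K, N-K)."""
    total = n + N
    succ = k + K
    denom = comb(total, n)
    p = 0.0
    for x in range(k, min(n, succ) + 1):
        if succ - x > N:
            continue
        p += comb(succ, x) * comb(total - succ, n - x) / denom
    return min(1.0, p)


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Textbook Holm step-down adjusted p-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * pvalues[idx])
        running = max(running, val)
        adjusted[idx] = running
    return adjusted
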