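"""Independent brute-force oracles used by the test suite.

These are written from the definitions, not from the package's code paths:
a full Gotoh dynamic-programming table for local protein alignment scores
(BLAST gap convention: a gap of length k costs open + k*extend) and the
set-based characterization of N50 (the largest contig length L such that
contigs of length >= L cover at least half the total).
"""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: float = 11, gap_extend: float = 1) -> float:
    """Optimal Smith-Waterman score by explicit three-matrix DP."""
    neg = float("-inf")
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in `a` (consumes b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in `b` (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            sub = _B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def n50_oracle(lengths) -> int:
    """N50 = max{L in lengths : 2 * sum(x for x >= L) >= total}."""
    total = sum(lengths)
    return max(L for L in set(lengths)
               if 2 * sum(x for x in lengths if x >= L) >= total)
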