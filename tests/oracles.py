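"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the library code paths they are used to check:
plain dynamic programming, no banding, no heuristics.
"""

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -5, -2
NEG = float("-inf")


def levenshtein_full_dp(a: str, b: str) -> int:
    """Unbanded Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def local_affine_score_oracle(a: str, b: str) -> int:
    """Smith-Waterman-Gotoh best local score with affine gaps: a gap of
    length L costs 5 + 2L, match +2, mismatch -3."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]  # best ending in a match/mismatch or 0
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (deletion in query b axis)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + GAP_EXTEND, H[i][j - 1] + GAP_OPEN + GAP_EXTEND)
            F[i][j] = max(F[i - 1][j] + GAP_EXTEND, H[i - 1][j] + GAP_OPEN + GAP_EXTEND)
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def global_identity_oracle(a: str, b: str) -> float:
    """Identity of two equal-length substitution-only variants (no gaps)."""
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
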