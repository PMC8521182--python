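"""Independent brute-force oracle for fingerprint alignment.

Enumerates every legal move sequence by plain top-down recursion (no
memoization, no tabulation) and returns the minimum cost. Kept deliberately
separate from the package's dynamic-programming implementation.
"""

import math


def brute_force_distance(x, y, G, both_fusions=True):
    x = list(x)
    y = list(y)

    def rec(i, j):
        if i == 0 and j == 0:
            return 0.0
        if i == 0 or j == 0:
            return math.inf
        xi, yj = x[i - 1], y[j - 1]
        d = abs(xi - yj)
        best = d + rec(i - 1, j - 1)  # match
        if i >= 2:
            best = min(best, abs(xi + x[i - 2] - yj) + rec(i - 2, j - 1))  # fuse X
            best = min(best, d + G + rec(i - 2, j - 1))  # skip X_{i-1}
        if j >= 2:
            best = min(best, d + G + rec(i - 1, j - 2))  # skip Y_{j-1}
            if both_fusions:
                best = min(best, abs(xi - yj - y[j - 2]) + rec(i - 1, j - 2))  # fuse Y
        return best

    return rec(len(x), len(y))
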