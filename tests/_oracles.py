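"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately written as plain O(N^2) Python loops,
independent of the vectorized library code paths it checks.
"""

import math


def chebyshev(a, b):
    return max(abs(x - y) for x, y in zip(a, b))


def apen_bruteforce(x, m, r, tau=1):
    """Approximate entropy by direct template counting (self-match included)."""
    x = list(map(float, x))
    N = len(x)

    def phi(mm):
        n = N - (mm - 1) * tau
        templ = [[x[i + tau * j] for j in range(mm)] for i in range(n)]
        total = 0.0
        for i in range(n):
            c = sum(1 for j in range(n) if chebyshev(templ[i], templ[j]) <= r)
            total += math.log(c / n)
        return total / n

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m, r, tau=1):
    """Sample entropy by direct pair counting (self-matches excluded)."""
    x = list(map(float, x))
    N = len(x)
    n = N - m * tau

    def paircount(mm):
        templ = [[x[i + tau * j] for j in range(mm)] for i in range(n)]
        c = 0
        for i in range(n):
            for j in range(i + 1, n):
                if chebyshev(templ[i], templ[j]) <= r:
                    c += 1
        return c

    B = paircount(m)
    A = paircount(m + 1)
    if A == 0 or B == 0:
        return math.nan
    return -math.log(A / B)


def time_domain_bruteforce(intervals):
    """SDNN / RMSSD / pNN50 / CVrr from their definitions, loop form."""
    x = list(map(float, intervals))
    n = len(x)
    mean = sum(x) / n
    sdnn = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    pnn50 = 100.0 * sum(1 for d in diffs if abs(d) > 50.0) / len(diffs)
    cvrr = 100.0 * sdnn / mean
    return sdnn, rmssd, pnn50, cvrr


def knn_bruteforce(train_X, train_y, query, k):
    """Exhaustive nearest-neighbour vote with the package's tie rules but an
    independent normalize-sort-vote path (1-D or 2-D lists)."""
    X = [list(map(float, row)) if hasattr(row, "__len__") else [float(row)] for row in train_X]
    q = list(map(float, query)) if hasattr(query, "__len__") else [float(query)]
    dims = len(X[0])
    los = [min(row[d] for row in X) for d in range(dims)]
    his = [max(row[d] for row in X) for d in range(dims)]
    spans = [hi - lo if hi > lo else 1.0 for lo, hi in zip(los, his)]
    Xn = [[(row[d] - los[d]) / spans[d] for d in range(dims)] for row in X]
    qn = [(q[d] - los[d]) / spans[d] for d in range(dims)]
    dists = [
        (math.sqrt(sum((a - b) ** 2 for a, b in zip(row, qn))), i)
        for i, row in enumerate(Xn)
    ]
    dists.sort()
    votes = [int(train_y[i]) for _, i in dists[:k]]
    n_pos = sum(votes)
    return 1 if n_pos >= k - n_pos else 0
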