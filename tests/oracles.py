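"""Independent oracles used by the test suite.

These are deliberately naive reimplementations (brute-force dynamic
programming, exact enumeration, closed forms) kept separate from the package
so they can certify it.
"""

from __future__ import annotations

import itertools

import numpy as np


def ddtw_brute(a, b, resample_len: int) -> float:
    """Brute-force DDTW: same definition as the package, written naively.

    Resample both sequences to ``resample_len`` points, estimate local
    derivatives, then run a plain table-filling DTW with squared local cost
    and divide the accumulated cost by the optimal path length (ties prefer
    the diagonal, then vertical, then horizontal predecessor).
    """

    def resample(x):
        x = np.asarray(x, dtype=float)
        return np.interp(np.linspace(0, len(x) - 1, resample_len),
                         np.arange(len(x)), x)

    def deriv(q):
        d = [0.0] * len(q)
        for i in range(1, len(q) - 1):
            d[i] = ((q[i] - q[i - 1]) + (q[i + 1] - q[i - 1]) / 2.0) / 2.0
        d[0], d[-1] = d[1], d[-2]
        return d

    da, db = deriv(resample(a)), deriv(resample(b))
    n, m = len(da), len(db)
    INF = float("inf")
    cost = [[INF] * m for _ in range(n)]
    plen = [[0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            c = (da[i] - db[j]) ** 2
            if i == 0 and j == 0:
                cost[i][j], plen[i][j] = c, 1
                continue
            options = []
            if i > 0 and j > 0:
                options.append((cost[i - 1][j - 1], plen[i - 1][j - 1]))
            if i > 0:
                options.append((cost[i - 1][j], plen[i - 1][j]))
            if j > 0:
                options.append((cost[i][j - 1], plen[i][j - 1]))
            best = min(options, key=lambda t: t[0])
            cost[i][j] = best[0] + c
            plen[i][j] = best[1] + 1
    return cost[n - 1][m - 1] / plen[n - 1][m - 1]


def compression_expectation(onsets) -> float:
    """Exact permutation expectation of the interval compression ratio.

    Enumerates every ordering of the onsets, averages the mean absolute
    consecutive difference, and divides by the actual mean interval.
    """
    onsets = list(onsets)
    actual = np.abs(np.diff(onsets)).mean()
    perm_means = [np.abs(np.diff(p)).mean()
                  for p in itertools.permutations(onsets)]
    return float(np.mean(perm_means) / actual)


def ols_slope(x, y) -> tuple[float, float]:
    """Closed-form OLS slope and its standard error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xc = x - x.mean()
    slope = float((xc @ y) / (xc @ xc))
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = resid @ resid / (n - 2)
    return slope, float(np.sqrt(s2 / (xc @ xc)))


def entropy_counts(counts, base=2.0) -> float:
    """Closed-form entropy of a frequency vector."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p) / np.log(base)).sum())
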