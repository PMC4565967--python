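"""Independent reference implementations used only to check the package.

These deliberately use naive formulations (exact rational arithmetic,
textbook sums, literal step-up definitions) and never call into the
package's own code paths.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational: sum of C(K,i) C(N-K,n-i) / C(N,n)."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def mid_ranks(values) -> np.ndarray:
    """Average ranks with mean-rank ties, built from a sorted scan."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson_textbook(x, y) -> float:
    """Pearson correlation from the raw-sum textbook formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x * x) - np.sum(x) ** 2) * np.sqrt(
        n * np.sum(y * y) - np.sum(y) ** 2
    )
    return float(num / den)


def spearman_oracle(x, y) -> float:
    """Rank-transform with mean ranks, then textbook Pearson."""
    return pearson_textbook(mid_ranks(x), mid_ranks(y))


def spearman_tiefree_closed_form(x, y) -> float:
    """1 - 6 sum(d^2) / (n (n^2 - 1)); valid only without ties."""
    rx = mid_ranks(x)
    ry = mid_ranks(y)
    n = len(rx)
    d = rx - ry
    return 1.0 - 6.0 * float(np.sum(d * d)) / (n * (n * n - 1))


def ols_slope_oracle(x, y) -> float:
    """Closed-form Sxy / Sxx from centred sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float(np.sum(xc * (y - y.mean())) / np.sum(xc * xc))


def bh_stepup_oracle(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
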