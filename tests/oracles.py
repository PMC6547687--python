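"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (and the scipy routines
behind them): the Mann-Whitney oracle enumerates group labelings, the
Fisher oracle enumerates hypergeometric tables, and the chi-square oracle
is the closed-form Pearson statistic.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom


def mannwhitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all labelings.

    Requires tie-free data.  Counts the fraction of C(n+m, n) group
    assignments whose U statistic is at least as far from its null mean
    as the observed one.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = np.array(x + y)
    n, m = len(x), len(y)
    mu = n * m / 2.0
    obs_u = float((np.array(x)[:, None] > np.array(y)[None, :]).sum())
    obs_dev = abs(obs_u - mu)
    hits = 0
    total = comb(n + m, n)
    for idx in combinations(range(n + m), n):
        xs = pooled[list(idx)]
        mask = np.ones(n + m, dtype=bool)
        mask[list(idx)] = False
        ys = pooled[mask]
        u = float((xs[:, None] > ys[None, :]).sum())
        if abs(u - mu) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def fisher_exact_p(a, b, c, d) -> float:
    """Two-sided Fisher exact p by summing hypergeometric table probabilities.

    All tables with the observed margins whose probability does not exceed
    the observed table's (within a 1e-7 relative tolerance) contribute.
    """
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    rv = hypergeom(n, row1, col1)
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(lo, hi + 1):
        p_k = rv.pmf(k)
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(1.0, float(total))


def bh_stepup(p_values):
    """Hand-executed BH step-up: q_i = min_{j: p_(j)>=p_(i)} m p_(j) / j."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        val = m * p[order[rank - 1]] / rank
        running = min(running, val)
        q_sorted[rank - 1] = min(1.0, running)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pearson_chi2(a, b, c, d):
    """Closed-form Pearson chi-square on a 2x2 table, df=1, no correction."""
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return stat, float(chi2_dist.sf(stat, df=1))
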