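"""Independent brute-force oracles used by the statistical tests.

These deliberately use different formulations from the package code (the
rank-sum identity for U; the literal step-up definition for BH) so that
agreement is a genuine cross-check.
"""

from itertools import combinations

import numpy as np
import pandas as pd


def brute_force_mann_whitney(x, y):
    """Two-sided exact p over all relabelings of the pooled values, via the
    rank-sum formulation of U (mid-ranks for ties)."""
    pooled = np.array(list(x) + list(y), dtype=float)
    n, m = len(x), len(y)
    ranks = pd.Series(pooled).rank(method="average").to_numpy()

    def u_from_ranks(idx):
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2

    mu = n * m / 2
    obs = u_from_ranks(range(n))
    total = extreme = 0
    for chosen in combinations(range(n + m), n):
        total += 1
        if abs(u_from_ranks(chosen) - mu) >= abs(obs - mu) - 1e-12:
            extreme += 1
    return obs, extreme / total


def brute_force_bh(p):
    """BH adjusted p-values from the literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running_min = min(running_min, p[i] * m / rank_from_end)
        q[i] = running_min
    return q
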