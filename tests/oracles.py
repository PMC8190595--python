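"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: naive O(n^2) ranking,
full enumeration of the Mann-Whitney U distribution, grid search over the
probability simplex, and a hand-rolled Benjamini-Hochberg step-up.
"""

from itertools import combinations

import numpy as np


def naive_percentile_ranks(values: np.ndarray) -> np.ndarray:
    """O(n^2) pairwise-comparison percentile ranks with average ties."""
    n = len(values)
    out = np.empty(n, dtype=float)
    for i, v in enumerate(values):
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        avg_rank = less + (equal + 1) / 2.0
        out[i] = (avg_rank - 0.5) / n
    return out


def mww_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group a: pairs where a-value exceeds b-value (ties half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mww_exact_p(a, b) -> float:
    """Two-sided exact MWW p by full enumeration of all label assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    u_obs = mww_u(a, b)
    idx = range(len(pooled))
    us = [mww_u(pooled[list(c)], np.delete(pooled, list(c)))
          for c in combinations(idx, n_a)]
    us = np.asarray(us)
    total = len(us)
    p_le = np.sum(us <= u_obs) / total
    p_ge = np.sum(us >= u_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def simplex_grid_best(C: np.ndarray, q: np.ndarray, step: float = 0.001) -> np.ndarray:
    """Dense grid search for min ||C w - q|| over the 2-simplex (2 centroids)."""
    assert C.shape[1] == 2
    best_w, best_err = None, np.inf
    for w1 in np.arange(0.0, 1.0 + step / 2, step):
        w = np.array([w1, 1.0 - w1])
        err = np.sum((C @ w - q) ** 2)
        if err < best_err:
            best_err, best_w = err, w
    return best_w


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Hand Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m, dtype=float)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
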