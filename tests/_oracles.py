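"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: rank-test p-values by
exhaustive enumeration of assignments, the maximum-margin hyperplane by
direct constrained optimization, and run detection by scanning all windows.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata


def mann_whitney_enum(x, y) -> float:
    """Two-sided Mann-Whitney p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n, m = len(x), len(y)

    def u_of(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_of(x, y)
    us = []
    idx = set(range(n + m))
    for c in combinations(sorted(idx), n):
        cs = set(c)
        xs = [pooled[i] for i in c]
        ys = [pooled[i] for i in sorted(idx - cs)]
        us.append(u_of(xs, ys))
    us = np.asarray(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def signed_rank_enum(diffs) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    r = rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    ws = np.empty(2**n)
    for mask in range(2**n):
        ws[mask] = sum(r[i] for i in range(n) if (mask >> i) & 1)
    p_le = (ws <= w_obs).mean()
    p_ge = (ws >= w_obs).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def max_margin_hyperplane(X, y) -> tuple[np.ndarray, float]:
    """Hard-margin maximum-margin separator via direct QP (SLSQP).

    ``y`` in {0, 1}; returns (w, b) with y=1 iff w.x + b > 0.
    """
    X = np.asarray(X, dtype=float)
    s = np.where(np.asarray(y) == 1, 1.0, -1.0)
    d = X.shape[1]

    def obj(wb):
        return 0.5 * np.dot(wb[:d], wb[:d])

    cons = [
        {"type": "ineq", "fun": (lambda wb, i=i: s[i] * (X[i] @ wb[:d] + wb[d]) - 1.0)}
        for i in range(len(X))
    ]
    res = minimize(obj, np.ones(d + 1), constraints=cons, method="SLSQP")
    assert res.success
    return res.x[:d], res.x[d]


def runs_scan(pvalues, alpha: float, min_run: int) -> list[tuple[int, int]]:
    """All maximal runs of indices with p < alpha and length >= min_run."""
    p = np.asarray(pvalues, dtype=float)
    out = []
    start = None
    for i, below in enumerate(p < alpha):
        if below and start is None:
            start = i
        if not below and start is not None:
            if i - start >= min_run:
                out.append((start, i - 1))
            start = None
    if start is not None and len(p) - start >= min_run:
        out.append((start, len(p) - 1))
    return out
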