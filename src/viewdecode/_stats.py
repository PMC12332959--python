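"""Shared nonparametric test helpers.

Conventions: exact null distributions on small, tie-free samples (Wilcoxon
signed-rank up to 25 pairs; Mann-Whitney whenever tie-free), otherwise a
normal approximation with tie and continuity corrections.  The continuity
correction is clipped at the distribution center so that a statistic
exactly at its null mean yields p = 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_EXACT_SIGNED_RANK_MAX_N = 25


def signed_rank_p(x, y=None) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    ``x`` may be the differences directly (``y=None``) or the first member
    of each pair.  Zero differences are dropped (Wilcoxon's convention).
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    tied = np.unique(np.abs(d)).size < n
    if n <= _EXACT_SIGNED_RANK_MAX_N and not tied:
        method = "exact"
        res = stats.wilcoxon(d, alternative="two-sided", method=method)
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return float(res.pvalue)


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact distribution when the pooled sample is tie-free; otherwise a
    tie-corrected normal approximation with a center-clipped continuity
    correction (identical samples give exactly p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.pvalue)
    ranks = stats.rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    mu = n * m / 2.0
    nn = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n * m / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1.0)))
    if var <= 0:
        return 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))
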