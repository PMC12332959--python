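"""Significance of d' time courses and cell-count subsampling curves.

Per bin, the 25 real d' estimates are compared with the 25 random-labeling
estimates by a two-sided Mann-Whitney U test.  A time course is declared
significant only where p stays strictly below 0.001 for at least five
consecutive 20-ms-spaced bins; no further multiple-comparison correction is
applied across bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import mann_whitney_p
from .decoding import decode_timecourse
from .population import PopulationDataset, plan_splits

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_RUN = 5


def per_bin_test(real, null) -> float:
    """Two-sided Mann-Whitney p-value of real vs null d' estimates.

    Exact distribution when the pooled values are tie-free (always the
    case for continuous d' estimates), tie-corrected normal approximation
    otherwise.
    """
    return mann_whitney_p(np.asarray(real, float), np.asarray(null, float))


def per_bin_tests(real_matrix: np.ndarray, null_matrix: np.ndarray) -> np.ndarray:
    """p-value per time bin for matched (n_bins, n_estimates) matrices."""
    real_matrix = np.asarray(real_matrix)
    null_matrix = np.asarray(null_matrix)
    if real_matrix.shape != null_matrix.shape:
        raise ValueError("real and null matrices must have identical shapes")
    return np.array(
        [per_bin_test(real_matrix[b], null_matrix[b]) for b in range(real_matrix.shape[0])]
    )


@dataclass
class SignificanceTrack:
    """Per-bin p-values and the intervals surviving the consecutive-bin rule."""

    bin_centers_ms: np.ndarray
    pvalues: np.ndarray
    intervals: list[tuple[float, float]]  # [start_ms, end_ms] by bin-center label
    alpha: float
    min_run: int

    def to_frame(self) -> pd.DataFrame:
        sig = np.zeros(len(self.pvalues), dtype=bool)
        for lo, hi in self.intervals:
            sig |= (self.bin_centers_ms >= lo) & (self.bin_centers_ms <= hi)
        return pd.DataFrame(
            {
                "bin_center_ms": self.bin_centers_ms,
                "p_value": self.pvalues,
                "in_significant_interval": sig,
            }
        )


def significant_runs(
    pvalues,
    bin_centers_ms,
    alpha: float = DEFAULT_ALPHA,
    min_run: int = DEFAULT_MIN_RUN,
) -> SignificanceTrack:
    """Maximal runs of >= ``min_run`` consecutive bins with p strictly < alpha.

    Bins with p exactly at alpha do not count ("below" is strict).
    Intervals are labeled by the bin centers of their first and last bin.
    """
    p = np.asarray(pvalues, dtype=float)
    centers = np.asarray(bin_centers_ms, dtype=float)
    if p.shape != centers.shape:
        raise ValueError("pvalues and bin_centers_ms must have the same length")
    below = p < alpha
    intervals: list[tuple[float, float]] = []
    i = 0
    n = len(p)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                intervals.append((float(centers[i]), float(centers[j])))
            i = j + 1
        else:
            i += 1
    return SignificanceTrack(
        bin_centers_ms=centers,
        pvalues=p,
        intervals=intervals,
        alpha=alpha,
        min_run=min_run,
    )


def subsample_curve(
    dataset: PopulationDataset,
    sizes,
    delta_deg: int,
    n_draws: int = 5,
    seed: int = 0,
    folds: int = 5,
    repeats: int = 5,
    split_seed: int = 0,
    **decoder_params,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decoding performance vs number of cells (neuron-dropping curve).

    For each roster size, ``n_draws`` random cell subsets are drawn without
    replacement and decoding is rerun (typically on a single wide 100-600 ms
    window dataset); reported per size as mean and SE (= SD/sqrt(n_draws))
    of the per-draw mean d'.

    Returns ``(curve, draws)``: the summary table and the per-draw values.
    """
    sizes = [int(s) for s in sizes]
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    if max(sizes) > dataset.n_cells:
        raise ValueError(
            f"requested size {max(sizes)} exceeds the {dataset.n_cells}-cell roster"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    plan = plan_splits(dataset.n_pseudo_trials, folds, repeats, split_seed)
    draw_rows = []
    for size in sizes:
        for d in range(n_draws):
            ids = list(rng.choice(dataset.roster, size=size, replace=False))
            sub = dataset.subset_cells(ids)
            mat = decode_timecourse(sub, delta_deg, plan, **decoder_params)
            draw_rows.append(
                {"size": size, "draw": d, "dprime": float(mat.mean())}
            )
    draws = pd.DataFrame(draw_rows)
    curve = (
        draws.groupby("size")["dprime"]
        .agg(
            mean_dprime="mean",
            se=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
        )
        .reset_index()
    )
    return curve, draws
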