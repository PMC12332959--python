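"""Sliding-window spike rates, baseline subtraction, per-cell normalization
and responsiveness screening.

Rates are computed in boxcar windows (default 100 ms) sliding in fixed steps
(default 20 ms); a bin labeled ``t`` covers ``[t - w/2, t + w/2)``.  The
default label grid runs -450..950 ms in 20 ms steps (71 bins).  Spontaneous
activity in the 500 ms preceding stimulus onset is subtracted per trial, and
each cell's rates are z-scored against its own pooled mean and standard
deviation before entering population vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._stats import signed_rank_p
from .simulate import SpikeData

DEFAULT_WINDOW_MS = 100.0
DEFAULT_STEP_MS = 20.0
DEFAULT_RANGE_MS = (-450.0, 950.0)
DEFAULT_BASELINE_MS = (-500.0, 0.0)
DEFAULT_EVOKED_MS = (0.0, 600.0)

STAGES = ("raw", "baseline_subtracted", "normalized")


def bin_centers(range_ms=DEFAULT_RANGE_MS, step_ms=DEFAULT_STEP_MS) -> np.ndarray:
    """Bin-center labels: ``floor((end - start)/step) + 1`` values."""
    start, end = range_ms
    n = int(np.floor((end - start) / step_ms + 1e-9)) + 1
    return start + step_ms * np.arange(n)


@dataclass
class RateTensor:
    """Spike rates (spikes/s) indexed by (cell, trial, time bin).

    The trial axis is shared across cells: trials are ordered by stimulus
    image (set, object, view) and then presentation number, so row ``j`` of
    every cell saw the same image.  ``trials`` describes that axis.
    """

    values: np.ndarray  # (n_cells, n_trials, n_bins)
    cells: pd.DataFrame  # axis 0: cell_id, area, animal, experience
    trials: pd.DataFrame  # axis 1: set_id, object_id, view_angle_deg, experience, rep
    bin_centers_ms: np.ndarray
    window_ms: float
    step_ms: float
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        n_cells, n_trials, n_bins = self.values.shape
        if len(self.cells) != n_cells or len(self.trials) != n_trials:
            raise ValueError("metadata tables do not match value dimensions")
        if len(self.bin_centers_ms) != n_bins:
            raise ValueError("bin_centers_ms does not match value dimensions")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def select_cells(self, mask_or_ids) -> "RateTensor":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            mask = mask_or_ids
        else:
            ids = set(mask_or_ids)
            mask = self.cells["cell_id"].isin(ids).to_numpy()
        return replace(
            self,
            values=self.values[mask],
            cells=self.cells.loc[mask].reset_index(drop=True),
        )


def _trial_axis(data: SpikeData) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Shared (image x presentation) trial axis; validates uniformity.

    Returns (images, trials, n_reps) where ``images`` has one row per
    stimulus image in canonical (set, object, view) order and ``trials``
    one row per (image, rep).
    """
    key = ["set_id", "object_id", "view_angle_deg"]
    images = (
        data.trials[key]
        .drop_duplicates()
        .sort_values(key)
        .reset_index(drop=True)
        .merge(data.catalog[key + ["experience"]], on=key, how="left")
    )
    counts = data.trials.groupby(["cell_id"] + key, sort=False).size()
    n_reps_all = counts.unique()
    if len(n_reps_all) != 1:
        raise ValueError(
            "trial counts differ across (cell, image) pairs; a uniform "
            f"count is required (found {sorted(n_reps_all)})"
        )
    n_reps = int(n_reps_all[0])
    per_cell_images = data.trials.groupby("cell_id", sort=False)[key].nunique()
    if (per_cell_images.prod(axis=1) != len(images)).any() and len(key) > 0:
        # nunique per column is a weak check; full check via group sizes
        sizes = data.trials.groupby("cell_id", sort=False).size()
        if (sizes != len(images) * n_reps).any():
            raise ValueError("some cells lack trials for some images")
    tmax = int(data.trials["trial_id"].max())
    if tmax != n_reps - 1 or int(data.trials["trial_id"].min()) != 0:
        raise ValueError("trial_id must run 0..n_reps-1 within each (cell, image)")
    trials = images.loc[images.index.repeat(n_reps)].reset_index(drop=True)
    trials["rep"] = np.tile(np.arange(n_reps), len(images))
    return images, trials, n_reps


def _flat_trial_index(
    data: SpikeData, images: pd.DataFrame, n_reps: int, frame: pd.DataFrame
) -> np.ndarray:
    """Map each row of ``frame`` (spikes or trials) to (cell, trial-row) flat index."""
    key = ["set_id", "object_id", "view_angle_deg"]
    if len(frame) == 0:
        return np.empty(0, dtype=int)
    cell_pos = pd.Series(np.arange(len(data.cells)), index=data.cells["cell_id"])
    ci = frame["cell_id"].map(cell_pos).to_numpy()
    merged = frame[key].merge(
        images[key].assign(_img=np.arange(len(images))), on=key, how="left"
    )
    ii = merged["_img"].to_numpy()
    if np.isnan(ci).any() if ci.dtype.kind == "f" else (ci < 0).any():
        raise ValueError("rows reference cells missing from the roster")
    if np.isnan(ii.astype(float)).any():
        raise ValueError("rows reference images missing from the catalog")
    return (
        ci.astype(int) * (len(images) * n_reps)
        + ii.astype(int) * n_reps
        + frame["trial_id"].to_numpy()
    )


def _window_counts(
    data: SpikeData, images: pd.DataFrame, n_reps: int, window: tuple[float, float]
) -> np.ndarray:
    """Spike counts per (cell, trial row) inside ``[window[0], window[1])``."""
    lo, hi = window
    sp = data.spikes
    times = sp["spike_time_ms"].to_numpy(dtype=float)
    in_win = (times >= lo) & (times < hi)
    flat = _flat_trial_index(data, images, n_reps, sp.loc[in_win])
    n_flat = len(data.cells) * len(images) * n_reps
    counts = np.bincount(flat, minlength=n_flat)
    return counts.reshape(len(data.cells), len(images) * n_reps)


def bin_rates(
    data: SpikeData,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
    range_ms: tuple[float, float] = DEFAULT_RANGE_MS,
) -> RateTensor:
    """Sliding-window spike rates for every (cell, trial).

    Every window must lie inside the recorded trial window.  Rate = spike
    count in the window divided by the window length.
    """
    if window_ms <= 0 or step_ms <= 0:
        raise ValueError("window_ms and step_ms must be positive")
    if len(data.cells) == 0:
        raise ValueError("empty cell roster")
    centers = bin_centers(range_ms, step_ms)
    half = window_ms / 2.0
    lo, hi = data.trial_window_ms
    if centers[0] - half < lo - 1e-9 or centers[-1] + half > hi + 1e-9:
        raise ValueError(
            f"analysis windows [{centers[0] - half}, {centers[-1] + half}) not "
            f"covered by trial window {data.trial_window_ms}"
        )
    t = data.spikes["spike_time_ms"].to_numpy(dtype=float)
    if (t < lo).any() or (t > hi).any():
        raise ValueError("spike times outside the trial window")

    images, trials, n_reps = _trial_axis(data)
    n_cells, n_img = len(data.cells), len(images)
    n_flat = n_cells * n_img * n_reps
    flat = _flat_trial_index(data, images, n_reps, data.spikes)

    ratio = window_ms / step_ms
    if abs(ratio - round(ratio)) < 1e-9:
        # elementary-bin path: count in step-sized bins, then boxcar-sum
        n_lead = int(round(ratio))
        n_elem = len(centers) - 1 + n_lead
        start = centers[0] - half
        elem = np.floor((t - start) / step_ms).astype(int)
        ok = (elem >= 0) & (elem < n_elem)
        counts = np.bincount(
            flat[ok] * n_elem + elem[ok], minlength=n_flat * n_elem
        ).reshape(n_flat, n_elem)
        csum = np.concatenate(
            [np.zeros((n_flat, 1), dtype=counts.dtype), np.cumsum(counts, axis=1)],
            axis=1,
        )
        win_counts = csum[:, n_lead:] - csum[:, :-n_lead]
    else:
        win_counts = np.empty((n_flat, len(centers)), dtype=int)
        for j, c in enumerate(centers):
            sel = (t >= c - half) & (t < c + half)
            win_counts[:, j] = np.bincount(flat[sel], minlength=n_flat)
    values = win_counts.reshape(n_cells, n_img * n_reps, len(centers)) / (
        window_ms / 1000.0
    )
    return RateTensor(
        values=values,
        cells=data.cells.reset_index(drop=True).copy(),
        trials=trials,
        bin_centers_ms=centers,
        window_ms=window_ms,
        step_ms=step_ms,
        stage="raw",
    )


def subtract_baseline(
    rates: RateTensor,
    data: SpikeData,
    baseline_window_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
) -> RateTensor:
    """Subtract each trial's spontaneous rate (default [-500, 0) ms).

    Negative values are permitted afterwards (response suppression).
    """
    lo, hi = baseline_window_ms
    wlo, whi = data.trial_window_ms
    if lo < wlo - 1e-9 or hi > whi + 1e-9:
        raise ValueError("baseline window not covered by the trial window")
    images, _, n_reps = _trial_axis(data)
    counts = _window_counts(data, images, n_reps, baseline_window_ms)
    baseline_rate = counts / ((hi - lo) / 1000.0)
    # align to the tensor's cell subset/order
    cell_pos = pd.Series(np.arange(len(data.cells)), index=data.cells["cell_id"])
    rows = cell_pos.loc[rates.cells["cell_id"]].to_numpy()
    values = rates.values - baseline_rate[rows][:, :, None]
    return replace(rates, values=values, stage="baseline_subtracted")


class CellNormalizer(BaseEstimator, TransformerMixin):
    """Per-cell z-scoring of spike rates.

    ``fit`` pools every (trial, bin) entry of a cell within the analysis
    range and records its mean ``r_mean_`` and sample standard deviation
    ``r_std_`` (ddof=1).  ``transform`` maps values to
    ``(r - r_mean) / r_std``; cells with zero variance cannot be normalized
    and are excluded with a warning (never silently passed through).
    """

    def __init__(self, std_floor: float = 1e-12):
        self.std_floor = std_floor

    def fit(self, rates: RateTensor, y=None) -> "CellNormalizer":
        X = rates.values.reshape(rates.n_cells, -1)
        if X.shape[1] < 2:
            raise ValueError("need at least two pooled entries per cell")
        self.r_mean_ = X.mean(axis=1)
        self.r_std_ = X.std(axis=1, ddof=1)
        self.excluded_ = self.r_std_ <= self.std_floor
        self.cell_ids_ = rates.cells["cell_id"].to_numpy().copy()
        self.stats_ = pd.DataFrame(
            {
                "cell_id": self.cell_ids_,
                "r_mean": self.r_mean_,
                "r_std": self.r_std_,
                "excluded": self.excluded_,
            }
        )
        return self

    def transform(self, rates: RateTensor) -> RateTensor:
        if not hasattr(self, "r_mean_"):
            raise RuntimeError("CellNormalizer is not fitted")
        if not np.array_equal(rates.cells["cell_id"].to_numpy(), self.cell_ids_):
            raise ValueError("tensor cell roster differs from the fitted roster")
        if self.excluded_.any():
            bad = list(self.cell_ids_[self.excluded_])
            warnings.warn(
                f"excluding {len(bad)} zero-variance cell(s) from normalization: {bad}"
            )
        keep = ~self.excluded_
        std = np.where(self.excluded_, 1.0, self.r_std_)
        values = (rates.values - self.r_mean_[:, None, None]) / std[:, None, None]
        out = replace(
            rates,
            values=values[keep],
            cells=rates.cells.loc[keep].reset_index(drop=True),
            stage="normalized",
        )
        return out


def normalize_cells(rates: RateTensor) -> tuple[RateTensor, pd.DataFrame]:
    """Z-score every cell; returns the normalized tensor and per-cell stats."""
    norm = CellNormalizer().fit(rates)
    return norm.transform(rates), norm.stats_


class ResponsivenessScreen(BaseEstimator):
    """Wilcoxon signed-rank screening of stimulus responsiveness.

    For every (cell, image): the per-trial evoked rate (default window
    [0, 600) ms) is compared against the same trial's spontaneous rate
    ([-500, 0) ms) with a paired two-sided signed-rank test.  P-values are
    Bonferroni-corrected over the images of each object set (m = 16 for a
    full set); a cell is responsive to a set if any image survives at
    ``alpha`` and responsive to an experience condition if responsive to at
    least one of its sets.
    """

    def __init__(
        self,
        evoked_window_ms: tuple[float, float] = DEFAULT_EVOKED_MS,
        baseline_window_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
        alpha: float = 0.05,
        min_trials: int = 6,
    ):
        self.evoked_window_ms = evoked_window_ms
        self.baseline_window_ms = baseline_window_ms
        self.alpha = alpha
        self.min_trials = min_trials

    def fit(self, data: SpikeData, y=None) -> "ResponsivenessScreen":
        images, _, n_reps = _trial_axis(data)
        if n_reps < self.min_trials:
            warnings.warn(
                f"only {n_reps} trials per image (< {self.min_trials}); the "
                "signed-rank test cannot reach Bonferroni-corrected "
                "significance -- all cells flagged non-responsive"
            )
        elo, ehi = self.evoked_window_ms
        blo, bhi = self.baseline_window_ms
        ev = _window_counts(data, images, n_reps, self.evoked_window_ms) / (
            (ehi - elo) / 1000.0
        )
        ba = _window_counts(data, images, n_reps, self.baseline_window_ms) / (
            (bhi - blo) / 1000.0
        )
        n_cells, n_img = len(data.cells), len(images)
        ev = ev.reshape(n_cells, n_img, n_reps)
        ba = ba.reshape(n_cells, n_img, n_reps)
        m_per_set = images.groupby("set_id").size()

        rows = []
        for ci in range(n_cells):
            for ii in range(n_img):
                if n_reps < self.min_trials:
                    p = np.nan
                else:
                    p = signed_rank_p(ev[ci, ii], ba[ci, ii])
                rows.append(p)
        report = images.loc[np.tile(np.arange(n_img), n_cells)].reset_index(drop=True)
        report.insert(0, "cell_id", np.repeat(data.cells["cell_id"].to_numpy(), n_img))
        report["p_raw"] = rows
        m = m_per_set.loc[report["set_id"]].to_numpy()
        report["p_adj"] = np.minimum(1.0, report["p_raw"] * m)
        report["significant"] = report["p_adj"] < self.alpha
        self.report_ = report
        self.set_level_ = (
            report.groupby(["cell_id", "set_id", "experience"])["significant"]
            .any()
            .rename("responsive")
            .reset_index()
        )
        self.n_trials_ = n_reps
        return self

    def responsive_cells(self, experience: str | None = None) -> list[str]:
        """Cells responsive to >= 1 image of >= 1 (matching) object set."""
        if not hasattr(self, "set_level_"):
            raise RuntimeError("ResponsivenessScreen is not fitted")
        tab = self.set_level_
        if experience is not None:
            tab = tab[tab["experience"] == experience]
        resp = tab.groupby("cell_id")["responsive"].any()
        return sorted(resp.index[resp])


def screen_responsive(
    data: SpikeData,
    evoked_window_ms: tuple[float, float] = DEFAULT_EVOKED_MS,
    alpha: float = 0.05,
) -> ResponsivenessScreen:
    """Fit a :class:`ResponsivenessScreen` with the given window and level."""
    return ResponsivenessScreen(evoked_window_ms=evoked_window_ms, alpha=alpha).fit(data)
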