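"""End-to-end analysis driver: spikes -> rates -> populations -> d' -> runs.

Ties the preprocessing, population, decoding and inference stages together
for a set of (area, experience, viewing-angle-difference) conditions, and
provides the single-window (100-600 ms) variants used for same-angle
baseline d' and cell-count subsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoding import DecodeResult, ViewGeneralizationDecoder
from .inference import SignificanceTrack, per_bin_tests, significant_runs
from .population import PopulationDataset, assemble
from .preprocessing import (
    DEFAULT_BASELINE_MS,
    DEFAULT_EVOKED_MS,
    DEFAULT_RANGE_MS,
    DEFAULT_STEP_MS,
    DEFAULT_WINDOW_MS,
    CellNormalizer,
    RateTensor,
    ResponsivenessScreen,
    bin_rates,
    subtract_baseline,
)
from .simulate import SpikeData

logger = logging.getLogger("viewdecode")

DEFAULT_SUMMARY_WINDOW_MS = (100.0, 600.0)


def preprocess(
    data: SpikeData,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
    range_ms: tuple[float, float] = DEFAULT_RANGE_MS,
    baseline_window_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
) -> RateTensor:
    """Raw binning, per-trial baseline subtraction, per-cell z-scoring."""
    rates = bin_rates(data, window_ms, step_ms, range_ms)
    rates = subtract_baseline(rates, data, baseline_window_ms)
    norm = CellNormalizer().fit(rates)
    out = norm.transform(rates)
    logger.info(
        "preprocessed %d cells x %d trials x %d bins (%d excluded as zero-variance)",
        out.n_cells,
        out.values.shape[1],
        out.n_bins,
        int(norm.excluded_.sum()),
    )
    return out


def single_window_rates(
    data: SpikeData, window_ms: tuple[float, float] = DEFAULT_SUMMARY_WINDOW_MS
) -> RateTensor:
    """One rate per trial over a single wide window (default 100-600 ms)."""
    lo, hi = window_ms
    width = hi - lo
    center = (lo + hi) / 2.0
    rates = bin_rates(data, window_ms=width, step_ms=width, range_ms=(center, center))
    return rates


def _condition_roster(
    data: SpikeData,
    screen: ResponsivenessScreen | None,
    area: str,
    experience: str,
    responsive_only: bool,
) -> list[str]:
    cells = data.cells
    mask = (cells["area"] == area) & (cells["experience"] == experience)
    ids = cells.loc[mask, "cell_id"].tolist()
    if responsive_only and screen is not None:
        resp = set(screen.responsive_cells(experience))
        ids = [c for c in ids if c in resp]
    return ids


@dataclass
class ConditionResult:
    area: str
    experience: str
    delta_deg: int
    decode: DecodeResult
    track: SignificanceTrack | None
    roster_size: int


@dataclass
class AnalysisResult:
    """Results of a multi-condition run plus bookkeeping."""

    conditions: dict[tuple[str, str, int], ConditionResult] = field(default_factory=dict)
    screen_report: pd.DataFrame | None = None

    @property
    def n_tested_bins(self) -> int:
        return sum(
            len(c.decode.bin_centers_ms)
            for c in self.conditions.values()
            if c.track is not None
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for (area, exp, delta), c in sorted(self.conditions.items()):
            intervals = c.track.intervals if c.track is not None else []
            rows.append(
                {
                    "area": area,
                    "experience": exp,
                    "delta_deg": delta,
                    "n_cells": c.roster_size,
                    "mean_dprime_100_600": _window_mean(c.decode),
                    "n_significant_intervals": len(intervals),
                    "significant_intervals": "; ".join(
                        f"{lo:g}-{hi:g}" for lo, hi in intervals
                    ),
                }
            )
        return pd.DataFrame(rows)


def _window_mean(
    res: DecodeResult, window: tuple[float, float] = DEFAULT_SUMMARY_WINDOW_MS
) -> float:
    sel = (res.bin_centers_ms >= window[0]) & (res.bin_centers_ms <= window[1])
    if not sel.any():
        return float("nan")
    return float(res.dprime_matrix[sel].mean())


def analyze(
    data: SpikeData,
    areas=("TE", "TEO"),
    experiences=("object_task", "across_set_task"),
    deltas=(30, 60, 90),
    n_pseudo_trials: int = 20,
    responsive_only: bool = True,
    evoked_window_ms: tuple[float, float] = DEFAULT_EVOKED_MS,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
    range_ms: tuple[float, float] = DEFAULT_RANGE_MS,
    assembly_seed: int = 0,
    split_seed: int = 0,
    null_seed: int = 101,
    alpha: float = 0.001,
    min_run: int = 5,
    **decoder_params,
) -> AnalysisResult:
    """Run the full time-resolved analysis for every requested condition.

    Conditions without cells (e.g. an experience never simulated) are
    skipped with a log message.
    """
    screen = None
    if responsive_only:
        screen = ResponsivenessScreen(evoked_window_ms=evoked_window_ms).fit(data)
    rates = preprocess(data, window_ms, step_ms, range_ms)
    result = AnalysisResult(
        screen_report=screen.report_ if screen is not None else None
    )
    available_exps = set(data.catalog["experience"])
    for area in areas:
        for exp in experiences:
            if exp not in available_exps:
                continue
            roster = _condition_roster(data, screen, area, exp, responsive_only)
            if not roster:
                logger.warning("no cells for condition (%s, %s); skipped", area, exp)
                continue
            dataset = assemble(
                rates,
                area=area,
                experience=exp,
                cell_ids=roster,
                n_pseudo_trials=n_pseudo_trials,
                seed=assembly_seed,
            )
            for delta in deltas:
                dec = ViewGeneralizationDecoder(
                    delta_deg=delta,
                    split_seed=split_seed,
                    null_seed=null_seed,
                    **decoder_params,
                ).fit(dataset)
                res = dec.result()
                res.condition = {"area": area, "experience": exp}
                track = None
                if res.null_matrix is not None:
                    pvals = per_bin_tests(res.dprime_matrix, res.null_matrix)
                    track = significant_runs(
                        pvals, res.bin_centers_ms, alpha=alpha, min_run=min_run
                    )
                result.conditions[(area, exp, delta)] = ConditionResult(
                    area=area,
                    experience=exp,
                    delta_deg=delta,
                    decode=res,
                    track=track,
                    roster_size=len(dataset.roster),
                )
                logger.info(
                    "condition (%s, %s, delta=%d): %d cells, %d significant interval(s)",
                    area,
                    exp,
                    delta,
                    len(dataset.roster),
                    len(track.intervals) if track else 0,
                )
    return result


def single_window_dataset(
    data: SpikeData,
    area: str,
    experience: str,
    cell_ids=None,
    window_ms: tuple[float, float] = DEFAULT_SUMMARY_WINDOW_MS,
    n_pseudo_trials: int = 20,
    assembly_seed: int = 0,
) -> PopulationDataset:
    """Assemble a one-bin dataset on a wide summary window (100-600 ms)."""
    rates = single_window_rates(data, window_ms)
    rates = subtract_baseline(rates, data)
    out = CellNormalizer().fit(rates).transform(rates)
    if cell_ids is None:
        cell_ids = data.cells.loc[
            (data.cells["area"] == area) & (data.cells["experience"] == experience),
            "cell_id",
        ].tolist()
    return assemble(
        out,
        area=area,
        experience=experience,
        cell_ids=cell_ids,
        n_pseudo_trials=n_pseudo_trials,
        seed=assembly_seed,
    )


def same_angle_dprime(
    data: SpikeData,
    area: str,
    experience: str,
    n_pseudo_trials: int = 20,
    responsive_only: bool = True,
    split_seed: int = 0,
    assembly_seed: int = 0,
    **decoder_params,
) -> float:
    """Held-out same-angle baseline d' on the 100-600 ms summary window."""
    cell_ids = None
    if responsive_only:
        screen = ResponsivenessScreen().fit(data)
        cell_ids = _condition_roster(data, screen, area, experience, True)
    dataset = single_window_dataset(
        data,
        area,
        experience,
        cell_ids=cell_ids,
        n_pseudo_trials=n_pseudo_trials,
        assembly_seed=assembly_seed,
    )
    dec = ViewGeneralizationDecoder(
        delta_deg=0, with_null=False, split_seed=split_seed, **decoder_params
    ).fit(dataset)
    return float(dec.dprime_matrix_.mean())
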