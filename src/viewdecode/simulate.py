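"""Synthetic spike-train generator emulating TE/TEO-like populations.

Cells are inhomogeneous-Poisson units with a spontaneous (baseline) rate, a
response latency, and a stimulus-locked evoked response with distinct early
and late phases.  Stimulus selectivity is controlled per cell by an
association strength ``alpha`` in [0, 1]:

    gain(image) = amplitude * (alpha * u[object] + (1 - alpha) * v[object, view])

where ``u`` is a per-object gain shared across views (view-invariant object
preference) and ``v`` is a view-specific gain.  With ``alpha = 1`` the
expected evoked rate is identical across the four views of an object; with
``alpha = 0`` and ``view_corr_length_deg = 0`` the per-view gains are
statistically independent across views.  A positive correlation length
gives the view-specific component a graded angular profile (nearby views
respond similarly), emulating the limited (~30 deg) viewing-angle tolerance
of view-tuned cells.

Populations mimicking anterior IT (area TE) cells driven by view-association
experience are drawn with high mean alpha; posterior IT (TEO)-like
populations with low mean alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .catalog import EXPERIENCES, OBJECT_IDS, VIEW_ANGLES, generate_catalog

SPIKE_COLUMNS = [
    "cell_id",
    "area",
    "animal",
    "experience",
    "set_id",
    "object_id",
    "view_angle_deg",
    "trial_id",
    "spike_time_ms",
]

AREAS = ("TE", "TEO")


@dataclass(frozen=True)
class GroupSpec:
    """One simulated cell group: cortical area x prior-experience condition."""

    area: str
    experience: str
    n_cells: int
    alpha_mean: float
    alpha_concentration: float = 20.0

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r}; expected one of {AREAS}")
        if self.experience not in EXPERIENCES:
            raise ValueError(
                f"unknown experience {self.experience!r}; expected one of {EXPERIENCES}"
            )
        if self.n_cells <= 0:
            raise ValueError(f"n_cells must be positive, got {self.n_cells}")
        if not 0.0 <= self.alpha_mean <= 1.0:
            raise ValueError(f"alpha_mean must be in [0, 1], got {self.alpha_mean}")


@dataclass
class SimConfig:
    """Simulation configuration.

    The trial window must cover the pre-stimulus baseline window [-500, 0)
    and every sliding analysis window; the default analysis grid spans bin
    centers -450..950 ms with 100 ms windows, hence (-500, 1000).
    """

    groups: list[GroupSpec]
    n_sets: int = 2
    set_experiences: list[str] | None = None
    n_trials_per_image: int = 20
    trial_window_ms: tuple[float, float] = (-500.0, 1000.0)
    rng_seed: int = 0
    animal: str = "sim"
    # firing-rate hyperparameters
    baseline_log_mean: float = math.log(5.0)  # median 5 spikes/s
    baseline_log_sd: float = 0.4
    amplitude_log_mean: float = math.log(10.0)  # median 10 spikes/s evoked gain
    amplitude_log_sd: float = 0.5
    tuning_gain_scale: float = 1.0  # 0 -> zero-signal (no evoked response)
    tuning_sigma: float = 1.0  # log-sd of object/view selectivity
    view_corr_length_deg: float = 31.0  # angular corr. length of view gains
    latency_range_ms: tuple[float, float] = (70.0, 110.0)
    phase_boundary_ms: float = 300.0
    early_phase_gain: float = 1.0
    late_phase_gain: float = 0.7
    stim_offset_ms: float = 600.0
    decay_tau_ms: float = 150.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("SimConfig needs at least one cell group")
        if self.n_trials_per_image < 2:
            raise ValueError("n_trials_per_image must be >= 2")
        lo, hi = self.trial_window_ms
        if lo > -500.0 or hi < 950.0:
            raise ValueError(
                f"trial window {self.trial_window_ms} must cover the baseline "
                "window [-500, 0) and the analysis range [-450, 950]"
            )
        if self.set_experiences is not None and len(self.set_experiences) != self.n_sets:
            raise ValueError("set_experiences must list one experience per set")
        if self.tuning_gain_scale < 0:
            raise ValueError("tuning_gain_scale must be >= 0")

    def make_catalog(self) -> pd.DataFrame:
        if self.set_experiences is not None:
            return generate_catalog(self.n_sets, self.set_experiences)
        needed = list(dict.fromkeys(g.experience for g in self.groups))
        exps = [needed[i % len(needed)] for i in range(self.n_sets)]
        return generate_catalog(self.n_sets, exps)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = [asdict(g) for g in self.groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["groups"] = [GroupSpec(**g) for g in d["groups"]]
        for key in ("trial_window_ms", "latency_range_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CellModel:
    """A single simulated unit and its expected-rate parameters."""

    cell_id: str
    area: str
    animal: str
    experience: str
    baseline_rate: float  # spikes/s
    association_strength: float  # alpha in [0, 1]
    view_tuning: pd.Series  # evoked gain (spikes/s) per (set, object, view)
    latency_ms: float
    early_phase_gain: float
    late_phase_gain: float
    phase_boundary_ms: float

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if (self.view_tuning < 0).any():
            raise ValueError("view tuning gains must be >= 0")
        if self.phase_boundary_ms <= self.latency_ms:
            raise ValueError("phase boundary must come after response latency")

    def expected_rate(
        self, image: tuple[str, int, int], t_ms: np.ndarray, config: SimConfig
    ) -> np.ndarray:
        """Expected firing rate (spikes/s) at times ``t_ms`` for one image."""
        t = np.asarray(t_ms, dtype=float)
        g = float(self.view_tuning.loc[image])
        rate = np.full(t.shape, self.baseline_rate)
        early = (t >= self.latency_ms) & (t < self.phase_boundary_ms)
        late = (t >= self.phase_boundary_ms) & (t < config.stim_offset_ms)
        tail = t >= config.stim_offset_ms
        rate[early] += self.early_phase_gain * g
        rate[late] += self.late_phase_gain * g
        rate[tail] += (
            self.late_phase_gain
            * g
            * np.exp(-(t[tail] - config.stim_offset_ms) / config.decay_tau_ms)
        )
        return rate


@dataclass
class SpikeData:
    """Spike events plus the trial, cell and stimulus bookkeeping tables.

    ``spikes`` has one row per spike; ``trials`` one row per stimulus
    presentation (so presentations with zero spikes are represented);
    ``cells`` one row per unit; ``catalog`` one row per image.  Spike times
    are in ms relative to stimulus onset (negative = pre-stimulus).
    """

    spikes: pd.DataFrame
    trials: pd.DataFrame
    cells: pd.DataFrame
    catalog: pd.DataFrame
    trial_window_ms: tuple[float, float]

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _view_correlation(config: SimConfig) -> np.ndarray:
    angles = np.asarray(VIEW_ANGLES, dtype=float)
    lam = config.view_corr_length_deg
    if lam <= 0:
        return np.eye(len(angles))
    d = np.abs(angles[:, None] - angles[None, :])
    return np.exp(-((d / lam) ** 2))


def _sample_alpha(rng: np.random.Generator, spec: GroupSpec, n: int) -> np.ndarray:
    m, c = spec.alpha_mean, spec.alpha_concentration
    if m <= 0.0:
        return np.zeros(n)
    if m >= 1.0:
        return np.ones(n)
    return rng.beta(m * c, (1.0 - m) * c, size=n)


def build_population(
    config: SimConfig, catalog: pd.DataFrame | None = None
) -> list[CellModel]:
    """Draw the cell population described by ``config``.

    Deterministic given ``config.rng_seed``.  Each cell receives an evoked
    gain for every image in the catalog; its association strength is drawn
    from its group's Beta distribution (point mass at 0 or 1 for boundary
    means).
    """
    if catalog is None:
        catalog = config.make_catalog()
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0]))

    sets = list(dict.fromkeys(catalog["set_id"]))
    n_obj, n_view = len(OBJECT_IDS), len(VIEW_ANGLES)
    corr = _view_correlation(config)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_view))
    sigma = config.tuning_sigma
    index = pd.MultiIndex.from_product(
        [sets, OBJECT_IDS, VIEW_ANGLES], names=["set_id", "object_id", "view_angle_deg"]
    )

    cells: list[CellModel] = []
    k = 0
    for spec in config.groups:
        alphas = _sample_alpha(rng, spec, spec.n_cells)
        for i in range(spec.n_cells):
            baseline = float(
                rng.lognormal(config.baseline_log_mean, config.baseline_log_sd)
            )
            amplitude = config.tuning_gain_scale * float(
                rng.lognormal(config.amplitude_log_mean, config.amplitude_log_sd)
            )
            alpha = float(alphas[i])
            # object gain shared across views; view gains angularly correlated
            zu = rng.standard_normal((len(sets), n_obj))
            zv = rng.standard_normal((len(sets), n_obj, n_view)) @ chol.T
            u = np.exp(sigma * zu - sigma**2 / 2.0)
            v = np.exp(sigma * zv - sigma**2 / 2.0)
            gains = amplitude * (alpha * u[:, :, None] + (1.0 - alpha) * v)
            tuning = pd.Series(gains.ravel(), index=index, name="gain")
            cells.append(
                CellModel(
                    cell_id=f"{spec.area}-{spec.experience[:6]}-{k:04d}",
                    area=spec.area,
                    animal=config.animal,
                    experience=spec.experience,
                    baseline_rate=baseline,
                    association_strength=alpha,
                    view_tuning=tuning,
                    latency_ms=float(rng.uniform(*config.latency_range_ms)),
                    early_phase_gain=config.early_phase_gain,
                    late_phase_gain=config.late_phase_gain,
                    phase_boundary_ms=config.phase_boundary_ms,
                )
            )
            k += 1
    return cells


def _segment_spikes(
    rng: np.random.Generator, rate: float, lo: float, hi: float, n_trials: int
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson spikes per trial on [lo, hi); times + trial ids."""
    dur_s = (hi - lo) / 1000.0
    if rate <= 0 or dur_s <= 0:
        return np.empty(0), np.empty(0, dtype=int)
    counts = rng.poisson(rate * dur_s, size=n_trials)
    total = int(counts.sum())
    times = rng.uniform(lo, hi, size=total)
    trial_ids = np.repeat(np.arange(n_trials), counts)
    return times, trial_ids


def _decay_spikes(
    rng: np.random.Generator,
    peak_rate: float,
    t0: float,
    t1: float,
    tau: float,
    n_trials: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponentially decaying rate ``peak_rate * exp(-(t - t0)/tau)`` on [t0, t1)."""
    span = t1 - t0
    if peak_rate <= 0 or span <= 0:
        return np.empty(0), np.empty(0, dtype=int)
    frac = 1.0 - math.exp(-span / tau)
    integral_s = peak_rate * (tau / 1000.0) * frac
    counts = rng.poisson(integral_s, size=n_trials)
    total = int(counts.sum())
    u = rng.uniform(0.0, 1.0, size=total)
    times = t0 - tau * np.log1p(-u * frac)
    trial_ids = np.repeat(np.arange(n_trials), counts)
    return times, trial_ids


def simulate_spikes(
    cells: list[CellModel],
    catalog: pd.DataFrame,
    config: SimConfig,
) -> SpikeData:
    """Simulate spike-event tables for every (cell, image) pair.

    Each pair receives exactly ``config.n_trials_per_image`` independent
    presentations (trials are i.i.d.; each emulates a first presentation).
    The rate is piecewise: baseline before the cell's latency, baseline plus
    early/late phase gain times the image gain during the stimulus epoch,
    and an exponentially decaying evoked tail after stimulus offset.
    Reproducible given ``config.rng_seed``.
    """
    if not cells:
        raise ValueError("no cells to simulate")
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    lo, hi = config.trial_window_ms
    n_tr = config.n_trials_per_image
    images = list(
        catalog[["set_id", "object_id", "view_angle_deg"]].itertuples(index=False)
    )

    frames: list[pd.DataFrame] = []
    trial_rows: list[pd.DataFrame] = []
    trial_ids_base = np.arange(n_tr)
    for cell in cells:
        for set_id, obj, view in images:
            g = float(cell.view_tuning.loc[(set_id, obj, view)])
            boundary = cell.phase_boundary_ms
            segs = [
                (cell.baseline_rate, lo, hi),  # spontaneous, whole trial
                (cell.early_phase_gain * g, cell.latency_ms, boundary),
                (cell.late_phase_gain * g, boundary, config.stim_offset_ms),
            ]
            times_list, trial_list = [], []
            for rate, a, b in segs:
                t, tr = _segment_spikes(rng, rate, a, min(b, hi), n_tr)
                times_list.append(t)
                trial_list.append(tr)
            t, tr = _decay_spikes(
                rng,
                cell.late_phase_gain * g,
                config.stim_offset_ms,
                hi,
                config.decay_tau_ms,
                n_tr,
            )
            times_list.append(t)
            trial_list.append(tr)
            times = np.concatenate(times_list)
            trials = np.concatenate(trial_list)
            order = np.lexsort((times, trials))
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": cell.cell_id,
                        "set_id": set_id,
                        "object_id": obj,
                        "view_angle_deg": view,
                        "trial_id": trials[order],
                        "spike_time_ms": times[order],
                    }
                )
            )
            trial_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell.cell_id,
                        "set_id": set_id,
                        "object_id": obj,
                        "view_angle_deg": view,
                        "trial_id": trial_ids_base,
                    }
                )
            )

    cells_df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "area": [c.area for c in cells],
            "animal": [c.animal for c in cells],
            "experience": [c.experience for c in cells],
            "association_strength": [c.association_strength for c in cells],
            "baseline_rate": [c.baseline_rate for c in cells],
        }
    )
    spikes = pd.concat(frames, ignore_index=True)
    spikes = spikes.merge(cells_df[["cell_id", "area", "animal", "experience"]], on="cell_id")
    spikes = spikes[SPIKE_COLUMNS]
    trials = pd.concat(trial_rows, ignore_index=True)
    return SpikeData(
        spikes=spikes,
        trials=trials,
        cells=cells_df,
        catalog=catalog.copy(),
        trial_window_ms=(lo, hi),
    )


def simulate(config: SimConfig) -> SpikeData:
    """Convenience: catalog + population + spikes from one config."""
    catalog = config.make_catalog()
    cells = build_population(config, catalog)
    return simulate_spikes(cells, catalog, config)
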