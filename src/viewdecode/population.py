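"""Pseudo-population vectors, train/test split plans and angle pairs.

Cells were recorded in separate sessions, so simultaneity is never assumed:
pseudo-trial ``j`` of an image takes, for each cell independently, that
cell's response on its own trial ``perm_c[j]`` after a per-cell random
permutation of the image's trial indices.  The roster fixes component order
of every population vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .catalog import VIEW_ANGLES
from .preprocessing import RateTensor

DEFAULT_N_PSEUDO_TRIALS = 20


@dataclass
class PopulationDataset:
    """Pseudo-population vectors per stimulus image.

    ``vectors`` is (n_images, n_pseudo_trials, n_bins, n_cells); component
    ``k`` of every vector comes from ``roster[k]``.
    """

    vectors: np.ndarray
    images: pd.DataFrame  # axis 0: set_id, object_id, view_angle_deg
    roster: list[str]
    condition: dict
    bin_centers_ms: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        n_img, _, n_bins, n_cells = self.vectors.shape
        if len(self.images) != n_img:
            raise ValueError("images table does not match vector dimensions")
        if len(self.roster) != n_cells:
            raise ValueError("roster length does not match vector dimensions")
        if len(self.bin_centers_ms) != n_bins:
            raise ValueError("bin_centers_ms does not match vector dimensions")

    @property
    def n_pseudo_trials(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_bins(self) -> int:
        return self.vectors.shape[2]

    @property
    def n_cells(self) -> int:
        return self.vectors.shape[3]

    def subset_cells(self, cell_ids) -> "PopulationDataset":
        """New dataset restricted to ``cell_ids`` (roster order = given order)."""
        pos = {c: i for i, c in enumerate(self.roster)}
        idx = [pos[c] for c in cell_ids]
        return PopulationDataset(
            vectors=self.vectors[:, :, :, idx],
            images=self.images,
            roster=list(cell_ids),
            condition=dict(self.condition),
            bin_centers_ms=self.bin_centers_ms,
            seed=self.seed,
        )


def assemble(
    rates: RateTensor,
    area: str | None = None,
    experience: str | None = None,
    cell_ids=None,
    n_pseudo_trials: int = DEFAULT_N_PSEUDO_TRIALS,
    seed: int = 0,
) -> PopulationDataset:
    """Assemble pseudo-population vectors from normalized rates.

    Cells are selected by ``area`` (and restricted to ``cell_ids`` when
    given, e.g. the responsive roster of a condition); images are the ones
    from object sets experienced under ``experience`` (all images when
    ``None``).  Deterministic under ``seed``.
    """
    if rates.stage != "normalized":
        raise ValueError(f"expected a normalized RateTensor, got stage {rates.stage!r}")

    cmask = np.ones(rates.n_cells, dtype=bool)
    if area is not None:
        cmask &= (rates.cells["area"] == area).to_numpy()
    if cell_ids is not None:
        wanted = list(cell_ids)
        have = set(rates.cells["cell_id"])
        missing = [c for c in wanted if c not in have]
        if missing:
            warnings.warn(f"excluding {len(missing)} roster cell(s) without data")
        cmask &= rates.cells["cell_id"].isin(wanted).to_numpy()
    if not cmask.any():
        raise ValueError("cell roster is empty after filtering")

    key = ["set_id", "object_id", "view_angle_deg"]
    trials = rates.trials
    imask = np.ones(len(trials), dtype=bool)
    if experience is not None:
        imask &= (trials["experience"] == experience).to_numpy()
    if not imask.any():
        raise ValueError(f"no images for experience {experience!r}")

    sub = trials.loc[imask]
    images = sub[key].drop_duplicates().sort_values(key).reset_index(drop=True)
    n_img = len(images)
    reps_per_image = len(sub) // n_img
    if n_pseudo_trials > reps_per_image:
        raise ValueError(
            f"n_pseudo_trials={n_pseudo_trials} exceeds the {reps_per_image} "
            "recorded trials per image"
        )

    cell_rows = np.flatnonzero(cmask)
    roster = rates.cells["cell_id"].to_numpy()[cell_rows].tolist()
    # trial rows of each image, in rep order
    img_rows = (
        sub.reset_index()
        .groupby(key, sort=True)["index"]
        .apply(lambda s: s.to_numpy())
    )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n_bins = rates.n_bins
    vectors = np.empty((n_img, n_pseudo_trials, n_bins, len(cell_rows)))
    for k, crow in enumerate(cell_rows):
        for i, (_, rows) in enumerate(img_rows.items()):
            perm = rng.permutation(len(rows))[:n_pseudo_trials]
            vectors[i, :, :, k] = rates.values[crow, rows[perm], :]
    return PopulationDataset(
        vectors=vectors,
        images=images,
        roster=roster,
        condition={"area": area, "experience": experience},
        bin_centers_ms=np.asarray(rates.bin_centers_ms),
        seed=seed,
    )


@dataclass
class SplitPlan:
    """5-fold x 5-repeat reassignment of pseudo-trials into train/test.

    Within a repeat the five test sets are disjoint and cover every
    pseudo-trial; the 25 (repeat, fold) pairs yield the 25 performance
    estimates per time bin.
    """

    n_pseudo_trials: int
    folds: int
    repeats: int
    seed: int
    assignments: list[tuple[int, int, np.ndarray, np.ndarray]] = field(
        default_factory=list
    )  # (repeat, fold, train_idx, test_idx)

    @property
    def n_estimates(self) -> int:
        return len(self.assignments)


def plan_splits(
    n_pseudo_trials: int, folds: int = 5, repeats: int = 5, seed: int = 0
) -> SplitPlan:
    """Plan ``repeats`` shuffled ``folds``-fold partitions of pseudo-trials.

    The same partition applies to every image (each image's pseudo-trials
    are spread across folds as evenly as possible).
    """
    if n_pseudo_trials < folds:
        raise ValueError(
            f"n_pseudo_trials={n_pseudo_trials} must be >= folds={folds}"
        )
    plan = SplitPlan(n_pseudo_trials, folds, repeats, seed)
    ss = np.random.SeedSequence([seed, 3]).generate_state(repeats)
    for r in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(ss[r] % (2**31)))
        for f, (train_idx, test_idx) in enumerate(kf.split(np.arange(n_pseudo_trials))):
            plan.assignments.append((r, f, train_idx, test_idx))
    return plan


@dataclass
class AnglePairSet:
    """Ordered (train_angle, test_angle) pairs at one angular difference."""

    delta_deg: int
    pairs: list[tuple[int, int]]

    @property
    def anchors(self) -> list[int]:
        return sorted({tr for tr, _ in self.pairs})

    def tests_for(self, anchor: int) -> list[int]:
        return [te for tr, te in self.pairs if tr == anchor]


def angle_pairs(delta_deg: int) -> AnglePairSet:
    """All ordered view-angle pairs with ``|train - test| = delta``.

    ``delta = 0`` gives the four identity pairs (the same-angle baseline);
    positive deltas include both rotation directions, e.g. 30 -> 6 pairs,
    90 -> 2 pairs.
    """
    if delta_deg not in (0, 30, 60, 90):
        raise ValueError(f"delta must be one of 0, 30, 60, 90; got {delta_deg}")
    pairs = [
        (a, b)
        for a in VIEW_ANGLES
        for b in VIEW_ANGLES
        if abs(a - b) == delta_deg and (delta_deg > 0 or a == b)
    ]
    return AnglePairSet(delta_deg=delta_deg, pairs=pairs)
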