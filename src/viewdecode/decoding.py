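"""One-vs-rest linear SVM decoding across viewing angles, scored by d'.

For each time bin, (repeat, fold) split, object set and anchor angle, a
linear soft-margin SVM (C = 1) learns hyperplanes separating each object
(labeled 1) from the other three (labeled 0) using training pseudo-trials
at the anchor angle.  The hyperplanes are then tested on held-out
pseudo-trials at viewing angles shifted by the requested angular
difference.  Performance is the signal-detection statistic

    d' = z(TP) - z(FP)

where TP (FP) is the proportion of target (non-target) test vectors
labeled 1 and z is the inverse standard-normal CDF (0.5 maps to z = 0);
proportions are clipped to [1/(2n), 1 - 1/(2n)] before the transform.
d' is averaged over the four target objects and all angle pairs of the
difference, giving 25 estimates per bin (5 folds x 5 repeats).

The matched null repeats the identical pipeline after randomly permuting
object-identity labels within every (set, angle) stratum, with a fresh
permutation per repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .catalog import OBJECT_IDS, VIEW_ANGLES
from .population import AnglePairSet, PopulationDataset, SplitPlan, angle_pairs, plan_splits


@dataclass
class ConfusionProportions:
    """True/false-positive proportions of one binary decoding test."""

    tp: float
    fp: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.tp <= 1.0 and 0.0 <= self.fp <= 1.0):
            raise ValueError("proportions must lie in [0, 1]")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one positive and one negative test vector")


def _clip_proportion(p: float, n: int) -> float:
    lo = 1.0 / (2.0 * n)
    return min(max(p, lo), 1.0 - lo)


def dprime(cp_or_tp, fp: float | None = None, n_pos: int | None = None, n_neg: int | None = None) -> float:
    """d' from true/false-positive proportions.

    Accepts a :class:`ConfusionProportions` or ``(tp, fp, n_pos, n_neg)``.
    Proportions of 0 and 1 are clipped by the 1/(2n) rule, with n the
    relevant test-vector count, so the result is always finite;
    ``d'(p, p) = 0`` for any clipped-equal proportions.
    """
    if isinstance(cp_or_tp, ConfusionProportions):
        cp = cp_or_tp
    else:
        cp = ConfusionProportions(float(cp_or_tp), float(fp), int(n_pos), int(n_neg))
    return float(
        ndtri(_clip_proportion(cp.tp, cp.n_pos)) - ndtri(_clip_proportion(cp.fp, cp.n_neg))
    )


def _make_svm(C: float, class_weight, max_iter: int) -> LinearSVC:
    # hinge-loss dual problem == standard soft-margin linear SVM;
    # large intercept_scaling keeps the bias effectively unregularized
    return LinearSVC(
        C=C,
        loss="hinge",
        dual=True,
        class_weight=class_weight,
        intercept_scaling=10.0,
        random_state=0,
        max_iter=max_iter,
        tol=1e-3,
    )


def train_hyperplane(
    train_vectors: np.ndarray,
    labels: np.ndarray,
    target_object_id=1,
    C: float = 1.0,
    class_weight=None,
    max_iter: int = 250,
) -> LinearSVC:
    """Fit the one-vs-rest hyperplane for ``target_object_id``.

    ``labels`` are object identities; vectors of the target are labeled 1,
    all others 0.  Test vectors are labeled 1 iff the decision value is
    positive.  Degenerate training sets (a single class, or identical
    vectors with mixed labels) raise or yield a constant decision; the
    latter is reported via a warning.
    """
    X = np.asarray(train_vectors, dtype=float)
    y = (np.asarray(labels) == target_object_id).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if np.allclose(X, X[0]):
        warnings.warn(
            "all training vectors identical with mixed labels; decision "
            "function is constant (majority rule)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = _make_svm(C, class_weight, max_iter).fit(X, y)
    return clf


def score(clf, test_vectors: np.ndarray, labels: np.ndarray, target_object_id) -> ConfusionProportions:
    """Confusion proportions of a fitted hyperplane on held-out vectors."""
    X = np.asarray(test_vectors, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    d = clf.decision_function(X)
    if d.ndim == 2:  # one-vs-rest multiclass: pick the target's column
        col = list(clf.classes_).index(target_object_id)
        d = d[:, col]
        labeled_one = d > 0
    else:
        labeled_one = d > 0
        if clf.classes_[1] != 1:  # binary: positive decision = class 1
            labeled_one = ~labeled_one
    pos = np.asarray(labels) == target_object_id
    if pos.all() or (~pos).all():
        raise ValueError("test set must contain target and non-target vectors")
    return ConfusionProportions(
        tp=float(labeled_one[pos].mean()),
        fp=float(labeled_one[~pos].mean()),
        n_pos=int(pos.sum()),
        n_neg=int((~pos).sum()),
    )


def make_null_label_maps(
    sets, repeats: int, seed: int
) -> dict[tuple[int, str, int], np.ndarray]:
    """Random object-label permutations per (repeat, set, angle) stratum.

    ``maps[(repeat, set_id, angle)]`` is an array ``perm`` with
    ``perm[k]`` the label assigned to object ``OBJECT_IDS[k]``; class
    balance (1 vs 3) is preserved by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    objs = np.asarray(OBJECT_IDS)
    maps = {}
    for r in range(repeats):
        for s in sets:
            for a in VIEW_ANGLES:
                maps[(r, s, a)] = objs[rng.permutation(len(objs))]
    return maps


def _decode_matrix(
    dataset: PopulationDataset,
    pairset: AnglePairSet,
    plan: SplitPlan,
    label_maps=None,
    C: float = 1.0,
    class_weight=None,
    pool_confusions: bool = False,
    train_scope: str = "anchor",
    max_iter: int = 250,
) -> np.ndarray:
    """d' matrix (n_bins x n_estimates); the engine behind real and null runs."""
    if train_scope not in ("anchor", "pooled"):
        raise ValueError("train_scope must be 'anchor' or 'pooled'")
    V = dataset.vectors
    n_img, n_pseudo, n_bins, n_cells = V.shape
    if plan.n_pseudo_trials != n_pseudo:
        raise ValueError("split plan does not match the dataset's pseudo-trial count")

    images = dataset.images
    sets = sorted(images["set_id"].unique())
    objs = np.asarray(OBJECT_IDS)
    # image rows per (set, angle), ordered by object id
    rows_by = {}
    for s in sets:
        for a in VIEW_ANGLES:
            sel = images.index[
                (images["set_id"] == s) & (images["view_angle_deg"] == a)
            ]
            ordered = sel[np.argsort(images.loc[sel, "object_id"].to_numpy())]
            if len(ordered) != len(objs):
                raise ValueError(
                    f"set {s!r} angle {a} must contain all {len(objs)} objects"
                )
            rows_by[(s, a)] = np.asarray(ordered)

    def labels_at(r: int, s, a: int) -> np.ndarray:
        if label_maps is None:
            return objs
        return label_maps[(r, s, a)]

    svm = _make_svm(C, class_weight, max_iter)
    out = np.empty((n_bins, plan.n_estimates))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for b in range(n_bins):
            Vb = V[:, :, b, :]
            for j, (r, f, tr_idx, te_idx) in enumerate(plan.assignments):
                dvals: list[float] = []
                hits = np.zeros(2)  # pooled-confusion accumulators (pos, neg)
                tots = np.zeros(2)
                for s in sets:
                    if train_scope == "pooled":
                        rows_all = np.concatenate(
                            [rows_by[(s, a)] for a in sorted(set(VIEW_ANGLES))]
                        )
                        Xtr = Vb[rows_all][:, tr_idx].reshape(-1, n_cells)
                        ytr = np.concatenate(
                            [
                                np.repeat(labels_at(r, s, a), len(tr_idx))
                                for a in sorted(set(VIEW_ANGLES))
                            ]
                        )
                        clf = svm.fit(Xtr, ytr)
                        anchor_clf = {a: clf for a in pairset.anchors}
                    else:
                        anchor_clf = {}
                        for a in pairset.anchors:
                            Xtr = Vb[rows_by[(s, a)]][:, tr_idx].reshape(-1, n_cells)
                            ytr = np.repeat(labels_at(r, s, a), len(tr_idx))
                            anchor_clf[a] = _make_svm(C, class_weight, max_iter).fit(
                                Xtr, ytr
                            )
                    for a in pairset.anchors:
                        clf = anchor_clf[a]
                        classes = clf.classes_
                        for te in pairset.tests_for(a):
                            Xte = Vb[rows_by[(s, te)]][:, te_idx].reshape(-1, n_cells)
                            yte = np.repeat(labels_at(r, s, te), len(te_idx))
                            D = clf.decision_function(Xte)
                            labeled = D > 0  # (n_test, 4) one column per class
                            for k, t in enumerate(classes):
                                pos = yte == t
                                tp = labeled[pos, k].mean()
                                fp = labeled[~pos, k].mean()
                                if pool_confusions:
                                    hits += (
                                        labeled[pos, k].sum(),
                                        labeled[~pos, k].sum(),
                                    )
                                    tots += (pos.sum(), (~pos).sum())
                                else:
                                    dvals.append(
                                        dprime(tp, fp, pos.sum(), (~pos).sum())
                                    )
                if pool_confusions:
                    out[b, j] = dprime(
                        hits[0] / tots[0], hits[1] / tots[1], int(tots[0]), int(tots[1])
                    )
                else:
                    out[b, j] = float(np.mean(dvals))
    return out


def decode_timecourse(
    dataset: PopulationDataset,
    delta_deg: int,
    plan: SplitPlan,
    **params,
) -> np.ndarray:
    """Real-label d' matrix (n_bins x n_estimates) at one angular difference."""
    return _decode_matrix(dataset, angle_pairs(delta_deg), plan, label_maps=None, **params)


def null_timecourse(
    dataset: PopulationDataset,
    delta_deg: int,
    plan: SplitPlan,
    null_seed: int = 101,
    **params,
) -> np.ndarray:
    """Random-labeling d' matrix: identical pipeline, permuted object labels."""
    pairset = angle_pairs(delta_deg)
    sets = sorted(dataset.images["set_id"].unique())
    maps = make_null_label_maps(sets, plan.repeats, null_seed)
    return _decode_matrix(dataset, pairset, plan, label_maps=maps, **params)


@dataclass
class DecodeResult:
    """Real and null d' matrices for one (area, experience, delta) condition."""

    condition: dict
    delta_deg: int
    bin_centers_ms: np.ndarray
    dprime_matrix: np.ndarray  # (n_bins, n_estimates)
    null_matrix: np.ndarray | None
    n_cells: int
    metadata: dict

    def to_frame(self) -> pd.DataFrame:
        """Long format: bin_center_ms, repeat, fold, dprime, is_null."""
        frames = []
        reps = self.metadata.get("repeats", 5)
        folds = self.metadata.get("folds", 5)
        rf = [(r, f) for r in range(reps) for f in range(folds)]
        for is_null, mat in ((False, self.dprime_matrix), (True, self.null_matrix)):
            if mat is None:
                continue
            n_bins, n_est = mat.shape
            frames.append(
                pd.DataFrame(
                    {
                        "bin_center_ms": np.repeat(self.bin_centers_ms, n_est),
                        "repeat": np.tile([r for r, _ in rf], n_bins),
                        "fold": np.tile([f for _, f in rf], n_bins),
                        "dprime": mat.ravel(),
                        "is_null": is_null,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


class ViewGeneralizationDecoder(BaseEstimator):
    """Time-resolved cross-view decoding of object identity.

    A scikit-learn-style estimator: ``fit`` consumes a
    :class:`~viewdecode.population.PopulationDataset` and computes the
    d' matrix (and, by default, its random-labeling null) at the configured
    viewing-angle difference.

    Parameters
    ----------
    delta_deg : 0, 30, 60 or 90
        Angular difference between training and testing views; 0 is the
        same-angle baseline (its "null" is degenerate and not computed
        unless asked).
    folds, repeats : int
        Cross-validation structure; 5 x 5 yields the canonical 25
        estimates per bin.
    C, class_weight : SVM hyperparameters (linear kernel, soft margin).
    pool_confusions : bool
        Pool hit/false-alarm counts over objects and angle pairs into one
        confusion table per estimate instead of averaging per-table d'.
    train_scope : "anchor" | "pooled"
        Train on one anchor angle at a time (default) or jointly on all
        four same-angle vector sets.

    Attributes
    ----------
    dprime_matrix_ : (n_bins, folds*repeats) real-label d' estimates.
    null_matrix_ : matching random-labeling estimates (or None).
    bin_centers_ms_, n_cells_, plan_ : bookkeeping of the fitted run.
    """

    def __init__(
        self,
        delta_deg: int = 30,
        folds: int = 5,
        repeats: int = 5,
        C: float = 1.0,
        class_weight=None,
        pool_confusions: bool = False,
        train_scope: str = "anchor",
        split_seed: int = 0,
        null_seed: int = 101,
        with_null: bool = True,
        max_iter: int = 250,
    ):
        self.delta_deg = delta_deg
        self.folds = folds
        self.repeats = repeats
        self.C = C
        self.class_weight = class_weight
        self.pool_confusions = pool_confusions
        self.train_scope = train_scope
        self.split_seed = split_seed
        self.null_seed = null_seed
        self.with_null = with_null
        self.max_iter = max_iter

    def _params(self) -> dict:
        return dict(
            C=self.C,
            class_weight=self.class_weight,
            pool_confusions=self.pool_confusions,
            train_scope=self.train_scope,
            max_iter=self.max_iter,
        )

    def fit(self, dataset: PopulationDataset, y=None) -> "ViewGeneralizationDecoder":
        if not isinstance(dataset, PopulationDataset):
            raise TypeError("fit expects a PopulationDataset")
        plan = plan_splits(
            dataset.n_pseudo_trials, self.folds, self.repeats, self.split_seed
        )
        self.plan_ = plan
        self.bin_centers_ms_ = np.asarray(dataset.bin_centers_ms)
        self.n_cells_ = dataset.n_cells
        self.dprime_matrix_ = decode_timecourse(
            dataset, self.delta_deg, plan, **self._params()
        )
        if self.with_null and self.delta_deg != 0:
            self.null_matrix_ = null_timecourse(
                dataset, self.delta_deg, plan, null_seed=self.null_seed, **self._params()
            )
        else:
            self.null_matrix_ = None
        return self

    def result(self) -> DecodeResult:
        if not hasattr(self, "dprime_matrix_"):
            raise RuntimeError("decoder is not fitted")
        return DecodeResult(
            condition={},
            delta_deg=self.delta_deg,
            bin_centers_ms=self.bin_centers_ms_,
            dprime_matrix=self.dprime_matrix_,
            null_matrix=self.null_matrix_,
            n_cells=self.n_cells_,
            metadata=dict(
                folds=self.folds,
                repeats=self.repeats,
                split_seed=self.split_seed,
                null_seed=self.null_seed,
                C=self.C,
                train_scope=self.train_scope,
            ),
        )
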