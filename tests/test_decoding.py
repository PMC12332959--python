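import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

import viewdecode as vd
from viewdecode.decoding import (
    ConfusionProportions,
    ViewGeneralizationDecoder,
    decode_timecourse,
    dprime,
    null_timecourse,
    score,
    train_hyperplane,
)
from viewdecode.pipeline import single_window_dataset
from viewdecode.population import plan_splits

from _oracles import max_margin_hyperplane


class TestDPrime:
    def test_chance_point_is_zero(self):
        assert dprime(0.5, 0.5, 10, 30) == 0.0

    def test_textbook_value(self):
        assert dprime(0.84, 0.16, 1000, 1000) == pytest.approx(
            norm.ppf(0.84) - norm.ppf(0.16), abs=1e-9
        )
        assert dprime(0.84, 0.16, 1000, 1000) == pytest.approx(1.9889, abs=1e-4)

    def test_clipping_of_perfect_proportions(self):
        # tp=1 (n=25) -> 49/50; fp=0 (n=25) -> 1/50
        assert dprime(1.0, 0.0, 25, 25) == pytest.approx(2 * norm.ppf(0.98), abs=1e-9)
        assert dprime(1.0, 0.0, 25, 25) == pytest.approx(4.107, abs=1e-3)
        # clipping n follows the relevant side's test count
        assert dprime(1.0, 0.0, 4, 12) == pytest.approx(
            norm.ppf(7 / 8) - norm.ppf(1 / 24), abs=1e-9
        )

    def test_equal_proportions_cancel(self):
        assert dprime(0.25, 0.25, 8, 24) == 0.0

    @given(
        k1=st.integers(1, 19),
        k2=st.integers(1, 19),
        kf=st.integers(1, 19),
    )
    def test_monotone_in_tp_and_fp(self, k1, k2, kf):
        n = 20
        d1, d2 = dprime(k1 / n, kf / n, n, n), dprime(k2 / n, kf / n, n, n)
        assert (d1 < d2) == (k1 < k2) or k1 == k2
        e1, e2 = dprime(kf / n, k1 / n, n, n), dprime(kf / n, k2 / n, n, n)
        assert (e1 > e2) == (k1 < k2) or k1 == k2

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            ConfusionProportions(1.2, 0.0, 5, 5)
        with pytest.raises(ValueError):
            ConfusionProportions(0.5, 0.5, 0, 5)


class TestHyperplane:
    def test_separable_clusters_perfectly_classified(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(size=(20, 3)) * 0.05 + [3, 0, 0],
                       rng.normal(size=(20, 3)) * 0.05 - [3, 0, 0]])
        y = np.array([1] * 20 + [2] * 20)
        clf = train_hyperplane(X, y, target_object_id=1)
        cp = score(clf, X, y, target_object_id=1)
        assert (cp.tp, cp.fp) == (1.0, 0.0)

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="single class"):
            train_hyperplane(X, np.ones(4), target_object_id=1)

    def test_identical_vectors_mixed_labels_reported(self):
        X = np.ones((6, 3))
        y = np.array([1, 1, 2, 2, 2, 2])
        with pytest.warns(UserWarning, match="identical"):
            clf = train_hyperplane(X, y, target_object_id=1)
        d = clf.decision_function(X)
        assert np.allclose(d, d[0])  # constant decision

    def test_matches_max_margin_oracle_on_5_points(self):
        X = np.array([[2.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [-2.0, 0.0], [0.0, 1.0]])
        y = np.array([1, 1, 0, 0, 0])
        w, b = max_margin_hyperplane(X, y)
        clf = train_hyperplane(X, y, target_object_id=1)
        probes = np.array(
            [[1.5, 0.5], [-1.5, 0.5], [0.5, 0.0], [-0.5, 0.0], [3.0, -1.0], [-3.0, 2.0]]
        )
        oracle_side = (probes @ w + b) > 0
        svm_side = clf.decision_function(probes) > 0
        np.testing.assert_array_equal(svm_side, oracle_side)


class TestScore:
    class _Stub:
        classes_ = np.array([0, 1])

        def __init__(self, decisions):
            self._d = np.asarray(decisions, dtype=float)

        def decision_function(self, X):
            return self._d

    def test_counting(self):
        y = np.array([1] * 8 + [2] * 12 + [3] * 12)
        decisions = np.r_[np.repeat([1.0, -1.0], [6, 2]), np.repeat([1.0, -1.0], [6, 18])]
        cp = score(self._Stub(decisions), np.zeros((32, 1)), y, target_object_id=1)
        assert cp.tp == pytest.approx(0.75)
        assert cp.fp == pytest.approx(0.25)
        assert (cp.n_pos, cp.n_neg) == (8, 24)

    def test_label_everything_one(self):
        y = np.array([1, 1, 2, 3])
        cp = score(self._Stub([5.0] * 4), np.zeros((4, 1)), y, 1)
        assert (cp.tp, cp.fp) == (1.0, 1.0)

    def test_empty_or_one_sided_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score(self._Stub([]), np.zeros((0, 1)), np.array([]), 1)
        with pytest.raises(ValueError, match="target"):
            score(self._Stub([1.0, 1.0]), np.zeros((2, 1)), np.array([1, 1]), 1)


@pytest.fixture(scope="module")
def tiny_window_dataset(small_sim):
    """Single-bin (100-600 ms) dataset of the 6-cell TE-like group."""
    return single_window_dataset(
        small_sim.data, "TE", "object_task", n_pseudo_trials=10
    )


class TestDecodeMatrices:
    def test_matrix_shape_and_determinism(self, tiny_window_dataset):
        plan = plan_splits(10, seed=5)
        m1 = decode_timecourse(tiny_window_dataset, 30, plan)
        m2 = decode_timecourse(tiny_window_dataset, 30, plan)
        assert m1.shape == (1, 25)
        np.testing.assert_array_equal(m1, m2)
        n1 = null_timecourse(tiny_window_dataset, 30, plan, null_seed=9)
        n2 = null_timecourse(tiny_window_dataset, 30, plan, null_seed=9)
        np.testing.assert_array_equal(n1, n2)
        n3 = null_timecourse(tiny_window_dataset, 30, plan, null_seed=10)
        assert not np.array_equal(n1, n3)

    def test_estimator_interface(self, tiny_window_dataset):
        dec = ViewGeneralizationDecoder(delta_deg=60, with_null=False, split_seed=2)
        assert dec.get_params()["delta_deg"] == 60
        dec.fit(tiny_window_dataset)
        assert dec.dprime_matrix_.shape == (1, 25)
        assert dec.null_matrix_ is None
        res = dec.result()
        frame = res.to_frame()
        assert len(frame) == 25
        assert set(frame["repeat"]) == set(range(5))
        dec0 = ViewGeneralizationDecoder(delta_deg=0, split_seed=2).fit(
            tiny_window_dataset
        )
        assert dec0.null_matrix_ is None  # degenerate at delta 0
        assert dec0.dprime_matrix_.mean() > 0.5

    def test_pooled_confusions_variant(self, tiny_window_dataset):
        plan = plan_splits(10, seed=5)
        pooled = decode_timecourse(tiny_window_dataset, 0, plan, pool_confusions=True)
        averaged = decode_timecourse(tiny_window_dataset, 0, plan)
        assert pooled.shape == averaged.shape
        # both detect the same structure, pooling is not wildly different
        assert np.corrcoef(pooled.ravel(), averaged.ravel())[0, 1] > 0.5

    def test_pooled_training_scope_runs(self, tiny_window_dataset):
        plan = plan_splits(10, seed=5)
        m = decode_timecourse(tiny_window_dataset, 90, plan, train_scope="pooled")
        assert m.shape == (1, 25)
        assert np.isfinite(m).all()


class TestTimecourseProperties:
    def test_no_prestimulus_significance(self, contrast_analysis):
        for (area, delta), res in contrast_analysis.items():
            for lo, hi in res.track.intervals:
                assert lo >= 0.0, f"{area} d{delta} run starts pre-stimulus at {lo}"

    def test_null_centered_near_zero(self, contrast_analysis):
        # the clipped z-transform biases each estimate slightly away from 0
        # (small unequal test counts); the permutation null must still sit
        # near zero relative to the real effect sizes
        for (area, delta), res in contrast_analysis.items():
            assert abs(res.null.mean()) < 0.4

    def test_same_angle_beats_large_rotation(self, small_sim):
        # delta 0 >= delta 90 for any alpha < 1 population
        plan = plan_splits(10, seed=1)
        for area in ("TE", "TEO"):
            ds = single_window_dataset(
                small_sim.data, area, "object_task", n_pseudo_trials=10
            )
            d0 = decode_timecourse(ds, 0, plan).mean()
            d90 = decode_timecourse(ds, 90, plan).mean()
            assert d0 >= d90
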