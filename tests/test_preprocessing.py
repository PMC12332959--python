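import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import viewdecode as vd
from viewdecode.preprocessing import (
    CellNormalizer,
    RateTensor,
    ResponsivenessScreen,
    bin_centers,
    bin_rates,
    normalize_cells,
    subtract_baseline,
)
from viewdecode._stats import signed_rank_p

from conftest import make_spike_data
from _oracles import signed_rank_enum


def make_tensor(values, stage="raw"):
    values = np.asarray(values, dtype=float)
    n_cells, n_trials, n_bins = values.shape
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "area": "TE",
            "animal": "sim",
            "experience": "object_task",
        }
    )
    trials = pd.DataFrame(
        {
            "set_id": "A",
            "object_id": 1,
            "view_angle_deg": 0,
            "experience": "object_task",
            "rep": np.arange(n_trials),
        }
    )
    return RateTensor(
        values=values,
        cells=cells,
        trials=trials,
        bin_centers_ms=np.arange(n_bins, dtype=float),
        window_ms=100.0,
        step_ms=20.0,
        stage=stage,
    )


class TestBinRates:
    def test_default_grid_has_71_bins(self):
        assert len(bin_centers()) == 71

    @given(
        start=st.integers(-450, 0),
        n_steps=st.integers(0, 80),
        step=st.sampled_from([5.0, 10.0, 20.0, 25.0]),
    )
    def test_bin_count_closed_form(self, start, n_steps, step):
        end = start + n_steps * step
        centers = bin_centers((start, end), step)
        assert len(centers) == int(np.floor((end - start) / step)) + 1

    def test_window_rate_from_counted_spikes(self):
        data = make_spike_data({(0, 1, 0, 0): [10.0, 50.0, 89.0]})
        # window centered at 50 ms covers [0, 100): all three spikes
        rates = bin_rates(data, window_ms=100.0, step_ms=20.0, range_ms=(50.0, 50.0))
        row = rates.trials
        idx = (
            (row["object_id"] == 1) & (row["view_angle_deg"] == 0) & (row["rep"] == 0)
        ).to_numpy()
        assert rates.values[0, idx, 0] == pytest.approx(30.0)
        # spike at 89 leaves the window centered at 30 ([-20, 80))
        rates2 = bin_rates(data, window_ms=100.0, step_ms=20.0, range_ms=(30.0, 30.0))
        assert rates2.values[0, idx, 0] == pytest.approx(20.0)

    def test_empty_trials_give_zero_rows(self):
        data = make_spike_data({(0, 1, 0, 0): [10.0]})
        rates = bin_rates(data)
        assert rates.values.shape == (1, 32, 71)
        assert (rates.values.sum(axis=2) > 0).sum() == 1  # only one trial has spikes

    def test_overlapping_windows_count_spike_multiple_times(self):
        data = make_spike_data({(0, 1, 0, 0): [0.0]})
        rates = bin_rates(data)
        idx = (
            (rates.trials["object_id"] == 1)
            & (rates.trials["view_angle_deg"] == 0)
            & (rates.trials["rep"] == 0)
        ).to_numpy()
        # a spike falls in window/step = 5 consecutive windows
        assert (rates.values[0, idx, :] > 0).sum() == 5

    def test_uncovered_range_rejected(self):
        data = make_spike_data({})
        with pytest.raises(ValueError, match="covered"):
            bin_rates(data, range_ms=(-450.0, 980.0))

    def test_non_divisible_step_fallback_matches(self):
        data = make_spike_data({(0, 2, 30, 1): [5.0, 40.0, 110.0, 300.0]})
        a = bin_rates(data, window_ms=100.0, step_ms=20.0, range_ms=(0.0, 400.0))
        b = bin_rates(data, window_ms=100.0, step_ms=20.0001, range_ms=(0.0, 400.0))
        # same first bin either way
        np.testing.assert_allclose(a.values[:, :, 0], b.values[:, :, 0])


class TestBaseline:
    def test_constant_train_zeroes_out(self):
        # 10 spikes/s homogeneous: identical baseline and in-window rates
        times = list(np.arange(-500.0, 1000.0, 100.0))
        data = make_spike_data({(0, o, v, t): times for o in range(1, 5)
                                for v in (0, 30, 60, 90) for t in range(2)})
        rates = bin_rates(data)
        out = subtract_baseline(rates, data)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)
        assert out.stage == "baseline_subtracted"

    def test_evoked_minus_baseline_arithmetic(self):
        # 10 spikes/s baseline; 50 spikes/s in [100, 300) from 20 ms spacing
        times = list(np.arange(-450.0, 0.0, 100.0)) + list(np.arange(101.0, 300.0, 20.0))
        data = make_spike_data({(0, 1, 0, 0): times})
        rates = bin_rates(data)
        out = subtract_baseline(rates, data)
        centers = out.bin_centers_ms
        idx_trial = (
            (out.trials["object_id"] == 1)
            & (out.trials["view_angle_deg"] == 0)
            & (out.trials["rep"] == 0)
        ).to_numpy()
        mid = (centers >= 150) & (centers <= 250)  # windows within [100, 300)
        np.testing.assert_allclose(out.values[0, idx_trial, :][0, mid], 40.0)
        # silent late windows sit below this trial's baseline: negative values
        late = centers >= 500
        np.testing.assert_allclose(out.values[0, idx_trial, :][0, late], -10.0)

    def test_baseline_window_must_be_recorded(self):
        data = make_spike_data({}, window=(-500.0, 1000.0))
        rates = bin_rates(data)
        data_short = make_spike_data({}, window=(-500.0, 1000.0))
        with pytest.raises(ValueError, match="baseline"):
            subtract_baseline(rates, data_short, baseline_window_ms=(-600.0, 0.0))


class TestNormalize:
    def test_three_point_example(self):
        rates = make_tensor(np.array([[[1.0], [2.0], [3.0]]]), stage="baseline_subtracted")
        out, stats = normalize_cells(rates)
        np.testing.assert_allclose(out.values.ravel(), [-1.0, 0.0, 1.0])
        assert stats.loc[0, "r_mean"] == pytest.approx(2.0)
        assert stats.loc[0, "r_std"] == pytest.approx(1.0)

    def test_pooled_moments_and_idempotence(self):
        rng = np.random.default_rng(7)
        rates = make_tensor(rng.gamma(2.0, 5.0, size=(4, 10, 13)))
        out, _ = normalize_cells(rates)
        flat = out.values.reshape(4, -1)
        np.testing.assert_allclose(flat.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(flat.std(axis=1, ddof=1), 1.0, atol=1e-9)
        again, _ = normalize_cells(out)
        np.testing.assert_allclose(again.values, out.values, atol=1e-9)

    def test_zero_variance_cell_excluded_with_warning(self):
        values = np.concatenate(
            [np.full((1, 5, 3), 7.0), np.random.default_rng(0).normal(size=(1, 5, 3))]
        )
        rates = make_tensor(values)
        with pytest.warns(UserWarning, match="zero-variance"):
            out, stats = normalize_cells(rates)
        assert out.n_cells == 1
        assert stats["excluded"].tolist() == [True, False]

    def test_roster_mismatch_rejected(self):
        rates = make_tensor(np.random.default_rng(1).normal(size=(2, 4, 3)))
        other = make_tensor(np.random.default_rng(2).normal(size=(3, 4, 3)))
        norm = CellNormalizer().fit(rates)
        with pytest.raises(ValueError, match="roster"):
            norm.transform(other)


class TestSignedRank:
    @given(st.integers(2, 8), st.integers(0, 4))
    def test_matches_exact_enumeration(self, n, case):
        rng = np.random.default_rng(1000 * n + case)
        d = rng.normal(size=n) * 5.0
        assert signed_rank_p(d) == pytest.approx(signed_rank_enum(d), abs=1e-12)

    def test_ties_fall_back_to_corrected_normal(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 2.0, -2.0, 3.0] * 4)
        p = signed_rank_p(d)
        assert 0.0 < p <= 1.0


class TestScreen:
    def test_rate_matched_windows_not_responsive(self):
        # 6 evoked spikes over 600 ms == 5 baseline spikes over 500 ms (10 sp/s)
        times = list(np.linspace(-450.0, -50.0, 5)) + list(np.linspace(30.0, 570.0, 6))
        data = make_spike_data(
            {(0, o, v, t): times for o in range(1, 5) for v in (0, 30, 60, 90)
             for t in range(8)},
            n_trials=8,
        )
        screen = ResponsivenessScreen().fit(data)
        assert (screen.report_["p_raw"] == 1.0).all()
        assert screen.responsive_cells() == []

    def test_bonferroni_adjustment_arithmetic(self):
        report = pd.DataFrame(
            {"p_raw": [0.004], "set_id": ["A"]}
        )  # m = 16 images in a set
        assert min(1.0, 0.004 * 16) == pytest.approx(0.064)
        # and on a fitted screen the relation holds row-wise
        data = make_spike_data(
            {(0, 1, 0, t): [50.0 * k for k in range(t + 1)] for t in range(8)},
            n_trials=8,
        )
        screen = ResponsivenessScreen().fit(data)
        np.testing.assert_allclose(
            screen.report_["p_adj"],
            np.minimum(1.0, screen.report_["p_raw"] * 16),
        )

    def test_strongly_driven_cells_detected(self, small_sim):
        screen = ResponsivenessScreen().fit(small_sim.data)
        resp = screen.responsive_cells("object_task")
        assert len(resp) >= small_sim.data.n_cells * 0.75

    def test_too_few_trials_flagged(self):
        data = make_spike_data({(0, 1, 0, 0): [10.0]}, n_trials=3)
        with pytest.warns(UserWarning, match="trials"):
            screen = ResponsivenessScreen().fit(data)
        assert screen.responsive_cells() == []
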