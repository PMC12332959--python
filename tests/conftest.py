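from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import viewdecode as vd
from viewdecode.decoding import decode_timecourse, null_timecourse
from viewdecode.inference import per_bin_tests, significant_runs
from viewdecode.pipeline import preprocess
from viewdecode.population import assemble, plan_splits
from viewdecode.simulate import SPIKE_COLUMNS

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_spike_data(
    spike_times: dict, n_trials: int = 2, n_cells: int = 1, window=(-500.0, 1000.0)
) -> vd.SpikeData:
    """Hand-built single-set SpikeData.

    ``spike_times[(cell, object_id, view, trial)] = [times...]``; every
    (cell, image) pair gets ``n_trials`` presentations.
    """
    catalog = vd.generate_catalog(1, ["object_task"])
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "area": "TE",
            "animal": "sim",
            "experience": "object_task",
        }
    )
    trial_rows = []
    spike_rows = []
    for _, img in catalog.iterrows():
        for ci in range(n_cells):
            for tr in range(n_trials):
                trial_rows.append(
                    (f"c{ci}", img.set_id, img.object_id, img.view_angle_deg, tr)
                )
                for t in spike_times.get(
                    (ci, img.object_id, img.view_angle_deg, tr), []
                ):
                    spike_rows.append(
                        (
                            f"c{ci}",
                            "TE",
                            "sim",
                            "object_task",
                            img.set_id,
                            img.object_id,
                            img.view_angle_deg,
                            tr,
                            float(t),
                        )
                    )
    trials = pd.DataFrame(
        trial_rows, columns=["cell_id", "set_id", "object_id", "view_angle_deg", "trial_id"]
    )
    spikes = pd.DataFrame(spike_rows, columns=SPIKE_COLUMNS)
    return vd.SpikeData(
        spikes=spikes, trials=trials, cells=cells, catalog=catalog, trial_window_ms=window
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small two-group simulation with real structure (12 cells, 8 trials)."""
    cfg = vd.contrast_config(seed=11, n_cells=6, n_trials_per_image=12)
    data = vd.simulate(cfg)
    rates = preprocess(data)
    return SimpleNamespace(config=cfg, data=data, rates=rates)


@pytest.fixture(scope="session")
def contrast_analysis():
    """Full time-resolved decode of the two-population contrast preset.

    TE-like (association-rich) and TEO-like (association-poor) populations,
    64 cells each, 20 pseudo-trials, deltas 30/60/90 with matched
    random-labeling nulls and consecutive-bin significance tracks.  Shared
    session-wide because it is the most expensive computation in the suite.
    """
    cfg = vd.contrast_config(seed=3)
    data = vd.simulate(cfg)
    rates = preprocess(data)
    plan = plan_splits(20, seed=0)
    out = {}
    for area in ("TE", "TEO"):
        ds = assemble(
            rates, area=area, experience="object_task", n_pseudo_trials=20, seed=0
        )
        for delta in (30, 60, 90):
            real = decode_timecourse(ds, delta, plan)
            null = null_timecourse(ds, delta, plan, null_seed=101)
            pvals = per_bin_tests(real, null)
            track = significant_runs(pvals, ds.bin_centers_ms)
            out[(area, delta)] = SimpleNamespace(
                real=real,
                null=null,
                pvals=pvals,
                track=track,
                centers=np.asarray(ds.bin_centers_ms),
            )
    return out
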