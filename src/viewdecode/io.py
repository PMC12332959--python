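"""On-disk formats: spike-event CSV + JSON sidecar, rate tensors, results.

The spike table is a plain CSV with one row per spike
(``cell_id,area,animal,experience,set_id,object_id,view_angle_deg,trial_id,
spike_time_ms``; times in ms relative to stimulus onset, negative allowed).
Cell metadata, the stimulus catalog, trial counts and the trial window live
in a JSON sidecar next to it, so presentations with zero spikes survive a
round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import RateTensor
from .simulate import SPIKE_COLUMNS, SpikeData

SPIKES_NAME = "spikes.csv"
SIDECAR_NAME = "spikes_meta.json"


def write_spike_data(data: SpikeData, outdir) -> Path:
    """Write ``spikes.csv`` + ``spikes_meta.json`` into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.spikes.to_csv(outdir / SPIKES_NAME, index=False, float_format="%.6f")
    counts = (
        data.trials.groupby(
            ["cell_id", "set_id", "object_id", "view_angle_deg"], sort=False
        )
        .size()
        .unique()
    )
    sidecar = {
        "trial_window_ms": list(data.trial_window_ms),
        "n_trials_per_image": int(counts[0]) if len(counts) == 1 else None,
        "cells": data.cells.to_dict(orient="records"),
        "catalog": data.catalog.to_dict(orient="records"),
    }
    if sidecar["n_trials_per_image"] is None:
        sidecar["trials"] = data.trials.to_dict(orient="records")
    (outdir / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return outdir / SPIKES_NAME


def read_spike_data(path) -> SpikeData:
    """Read a spike table written by :func:`write_spike_data`.

    ``path`` may be the directory or the ``spikes.csv`` file itself.
    """
    path = Path(path)
    if path.is_dir():
        csv_path, sidecar_path = path / SPIKES_NAME, path / SIDECAR_NAME
    else:
        csv_path, sidecar_path = path, path.parent / SIDECAR_NAME
    spikes = pd.read_csv(csv_path)
    missing = [c for c in SPIKE_COLUMNS if c not in spikes.columns]
    if missing:
        raise ValueError(f"spike table lacks required column(s): {missing}")
    meta = json.loads(sidecar_path.read_text())
    cells = pd.DataFrame(meta["cells"])
    catalog = pd.DataFrame(meta["catalog"])
    if meta.get("n_trials_per_image"):
        n = int(meta["n_trials_per_image"])
        key = ["set_id", "object_id", "view_angle_deg"]
        base = catalog[key]
        trials = (
            pd.MultiIndex.from_product(
                [cells["cell_id"], range(len(base)), range(n)],
                names=["cell_id", "_img", "trial_id"],
            )
            .to_frame(index=False)
            .merge(base.assign(_img=np.arange(len(base))), on="_img")
            .drop(columns="_img")[["cell_id"] + key + ["trial_id"]]
        )
    else:
        trials = pd.DataFrame(meta["trials"])
    return SpikeData(
        spikes=spikes,
        trials=trials,
        cells=cells,
        catalog=catalog,
        trial_window_ms=tuple(meta["trial_window_ms"]),
    )


def write_rate_tensor(rates: RateTensor, prefix) -> None:
    """Dense array (.npy) plus a JSON header describing the axes."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(prefix.with_suffix(".npy"), rates.values)
    header = {
        "dimension_order": ["cell", "trial", "time_bin"],
        "stage": rates.stage,
        "window_ms": rates.window_ms,
        "step_ms": rates.step_ms,
        "bin_centers_ms": list(map(float, rates.bin_centers_ms)),
        "cells": rates.cells.to_dict(orient="records"),
        "trials": rates.trials.to_dict(orient="records"),
    }
    prefix.with_suffix(".json").write_text(json.dumps(header))


def read_rate_tensor(prefix) -> RateTensor:
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    return RateTensor(
        values=np.load(prefix.with_suffix(".npy")),
        cells=pd.DataFrame(header["cells"]),
        trials=pd.DataFrame(header["trials"]),
        bin_centers_ms=np.asarray(header["bin_centers_ms"]),
        window_ms=header["window_ms"],
        step_ms=header["step_ms"],
        stage=header["stage"],
    )
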