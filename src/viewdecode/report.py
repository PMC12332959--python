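"""Figures and summaries from decode outputs.

Time-course panels show the mean +/- SE (over the 25 estimates) of the real
and random-labeling d' per bin, with thick horizontal bars marking the
intervals that survive the consecutive-bin rule.  Subsampling panels show
mean +/- SE of d' against the number of cells.  Every figure's plotted
values are also written as CSV, so figures are never the only record.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _mean_se(frame: pd.DataFrame) -> pd.DataFrame:
    g = frame.groupby("bin_center_ms")["dprime"]
    out = g.agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
    return out.reset_index()


def plot_timecourse(
    frame: pd.DataFrame,
    intervals: list[tuple[float, float]],
    title: str,
    png_path: Path,
    csv_path: Path | None = None,
) -> pd.DataFrame:
    """Plot one condition's d' time course from its long-format table."""
    real = _mean_se(frame[~frame["is_null"]])
    null = _mean_se(frame[frame["is_null"]]) if frame["is_null"].any() else None

    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(real["bin_center_ms"], real["mean"], "k-", lw=1.5, label="d'")
    ax.fill_between(
        real["bin_center_ms"],
        real["mean"] - real["se"],
        real["mean"] + real["se"],
        color="0.4",
        alpha=0.5,
        lw=0,
    )
    merged = real.rename(columns={"mean": "dprime_mean", "se": "dprime_se"})
    if null is not None:
        ax.plot(null["bin_center_ms"], null["mean"], "k:", lw=1.2, label="random labeling")
        ax.fill_between(
            null["bin_center_ms"],
            null["mean"] - null["se"],
            null["mean"] + null["se"],
            color="0.8",
            alpha=0.7,
            lw=0,
        )
        merged["null_mean"] = null["mean"].to_numpy()
        merged["null_se"] = null["se"].to_numpy()
    y0 = ax.get_ylim()[0]
    for lo, hi in intervals:
        ax.plot([lo, hi], [y0, y0], "k-", lw=4, solid_capstyle="butt")
    ax.axvline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("time from stimulus onset (ms)")
    ax.set_ylabel("d'")
    ax.set_title(title, fontsize=10)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    if csv_path is not None:
        merged.to_csv(csv_path, index=False)
    return merged


def plot_subsample(
    curve: pd.DataFrame, title: str, png_path: Path, csv_path: Path | None = None
) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(
        curve["size"], curve["mean_dprime"], yerr=curve["se"], fmt="ko-", capsize=3
    )
    ax.set_xlabel("number of cells")
    ax.set_ylabel("d' (100-600 ms)")
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    if csv_path is not None:
        curve.to_csv(csv_path, index=False)


def make_report(results_dir, outdir) -> list[Path]:
    """Render figures + CSVs for every decode output found in ``results_dir``.

    Partial results are reported as far as they go (missing pieces are
    listed in the returned manifest's warnings file rather than failing).
    """
    results_dir, outdir = Path(results_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings_log: list[str] = []

    summary_path = results_dir / "run_summary.json"
    summary = json.loads(summary_path.read_text()) if summary_path.exists() else {}
    if not summary:
        warnings_log.append("run_summary.json missing; deriving conditions from files")

    for csv_file in sorted(results_dir.glob("dprime_*.csv")):
        tag = csv_file.stem[len("dprime_") :]
        frame = pd.read_csv(csv_file)
        intervals = []
        sig = summary.get("conditions", {}).get(tag, {}).get("significant_intervals")
        if sig is None:
            sig_file = results_dir / f"significance_{tag}.json"
            if sig_file.exists():
                sig = json.loads(sig_file.read_text()).get("intervals", [])
            else:
                warnings_log.append(f"no significance info for {tag}")
                sig = []
        intervals = [tuple(iv) for iv in sig]
        png = outdir / f"timecourse_{tag}.png"
        plot_timecourse(
            frame, intervals, tag.replace("_", " "), png, outdir / f"timecourse_{tag}.csv"
        )
        written.append(png)

    for csv_file in sorted(results_dir.glob("subsample_*.csv")):
        tag = csv_file.stem[len("subsample_") :]
        curve = pd.read_csv(csv_file)
        png = outdir / f"subsample_{tag}.png"
        plot_subsample(curve, tag.replace("_", " "), png, outdir / f"subsample_{tag}.csv")
        written.append(png)

    if summary:
        pd.DataFrame(
            [
                dict(condition=tag, **{k: v for k, v in info.items() if k != "significant_intervals"},
                     significant_intervals="; ".join(f"{lo:g}-{hi:g}" for lo, hi in info.get("significant_intervals", [])))
                for tag, info in summary.get("conditions", {}).items()
            ]
        ).to_csv(outdir / "summary_table.csv", index=False)
        written.append(outdir / "summary_table.csv")
    if warnings_log:
        (outdir / "report_warnings.txt").write_text("\n".join(warnings_log) + "\n")
    return written
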