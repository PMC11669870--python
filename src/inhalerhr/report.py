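"""Figure rendering for a completed pipeline run.

Reads the CSV/JSON artifacts a run directory already contains — it never
recomputes analysis numbers — and renders the five standard figures:

1. hourly heart rate by LABA status,
2. inhalations by hour of day and inhaler type,
3. event-aligned heart rate around LABA (maintenance) actuations,
4. steps around SABA actuations on event vs control days,
5. SABA heart-rate difference: raw minutes, smooth, and the threshold band.

Rendering is best-effort: a figure whose inputs are missing is skipped with
a log note, and each figure is written as both vector (SVG) and raster
(PNG) output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .store import read_event_csv

__all__ = ["render_report"]

log = logging.getLogger("inhalerhr")


def _save(fig, outdir: Path, stem: str, written: list[str]) -> None:
    for ext in ("svg", "png"):
        fig.savefig(outdir / f"{stem}.{ext}", dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(stem)


def render_report(run_dir, figure_dir=None) -> list[str]:
    """Render every figure whose inputs exist in ``run_dir``.

    Returns the list of figure stems written.
    """
    run_dir = Path(run_dir)
    outdir = Path(figure_dir) if figure_dir else run_dir / "figures"
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    hourly = run_dir / "hourly_group_curve.csv"
    if hourly.exists():
        df = pd.read_csv(hourly, index_col=0)
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(df.index, df["laba_mean"], marker="o", label="LABA")
        ax.plot(df.index, df["non_laba_mean"], marker="s", label="no LABA")
        ax.set_xlabel("hour of day")
        ax.set_ylabel("mean heart rate (bpm)")
        ax.set_title("Hourly heart rate by LABA status (patient-first means)")
        ax.legend()
        _save(fig, outdir, "fig1_hourly_group_curve", written)
    else:
        log.info("figure 1 skipped: %s missing", hourly)

    events_csv = run_dir / "data" / "events.csv"
    if events_csv.exists():
        logs = read_event_csv(events_csv)
        rows = [
            {"hour": ts.hour, "inhaler_type": it}
            for elog in logs.values()
            for ts, it in zip(elog.events["timestamp"], elog.events["inhaler_type"])
        ]
        if rows:
            counts = (
                pd.DataFrame(rows)
                .value_counts(["hour", "inhaler_type"])
                .unstack(fill_value=0)
                .reindex(range(24), fill_value=0)
            )
            fig, ax = plt.subplots(figsize=(7, 4))
            counts.plot.bar(stacked=True, ax=ax, width=0.9)
            ax.set_xlabel("hour of day")
            ax.set_ylabel("inhalations")
            ax.set_title("Inhalations by hour and inhaler type")
            _save(fig, outdir, "fig2_inhalations_by_hour", written)
    else:
        log.info("figure 2 skipped: %s missing", events_csv)

    laba_curve = run_dir / "laba_difference_curve.csv"
    if laba_curve.exists():
        df = pd.read_csv(laba_curve)
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.plot(df["relative_minute"], df["event_mean"], lw=0.6)
        ax.axvline(0, color="k", lw=0.8, ls="--")
        ax.set_xlabel("minutes from LABA actuation")
        ax.set_ylabel("mean heart rate (bpm)")
        ax.set_title("Heart rate around maintenance (LABA) actuations — no control subtraction")
        _save(fig, outdir, "fig3_laba_event_aligned", written)
    else:
        log.info("figure 3 skipped: %s missing", laba_curve)

    steps_curve = run_dir / "saba_steps_curve.csv"
    if steps_curve.exists():
        df = pd.read_csv(steps_curve)
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.plot(df["relative_minute"], df["event_mean"], label="SABA days", lw=0.8)
        ax.plot(df["relative_minute"], df["control_mean"], label="control days", lw=0.8)
        ax.axvline(0, color="k", lw=0.8, ls="--")
        ax.set_xlabel("minutes from SABA actuation")
        ax.set_ylabel("mean steps per minute")
        ax.set_title("Steps around SABA actuation, event vs control days")
        ax.legend()
        _save(fig, outdir, "fig4_steps_around_saba", written)
    else:
        log.info("figure 4 skipped: %s missing", steps_curve)

    saba_curve = run_dir / "saba_difference_curve.csv"
    if saba_curve.exists():
        df = pd.read_csv(saba_curve)
        fig, ax = plt.subplots(figsize=(8, 4.5))
        ax.plot(
            df["relative_minute"], df["difference"], ".", ms=2, alpha=0.5,
            label="minute difference",
        )
        smooth_path = run_dir / "saba_smoothed.csv"
        if smooth_path.exists():
            sm = pd.read_csv(smooth_path)
            ax.plot(sm.iloc[:, 0], sm.iloc[:, 1], lw=1.5, label="smoothed")
        xs_path = run_dir / "saba_crossings.json"
        if xs_path.exists():
            xs = json.loads(xs_path.read_text())
            ax.axhline(xs["threshold_bpm"], color="r", lw=0.8, ls=":",
                       label=f"{xs['threshold_bpm']:g} bpm threshold")
        ax.axvline(0, color="k", lw=0.8, ls="--")
        ax.set_xlabel("minutes from SABA actuation")
        ax.set_ylabel("heart-rate difference (bpm)")
        ax.set_title("SABA event-day minus control-day heart rate")
        ax.legend()
        _save(fig, outdir, "fig5_saba_difference", written)
    else:
        log.info("figure 5 skipped: %s missing", saba_curve)

    if not written:
        (outdir / "README.txt").write_text(
            "No figures rendered: run the pipeline first so the analysis "
            "artifacts exist in this directory.\n"
        )
        log.info("no figures rendered for %s", run_dir)
    return written
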