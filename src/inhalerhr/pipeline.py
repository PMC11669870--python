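"""Run configuration and end-to-end orchestration.

A single structured YAML config drives both cohort generation and analysis,
so a full study run is reproducible from one file + seed:

.. code-block:: yaml

    seed: 1
    output_dir: out
    generator: {n_patients: 10, days_per_patient: 30}
    wear_threshold_min: 10080
    event_study: {threshold_bpm: 5, step_filter: true, span: 0.15}

Alternatively ``inputs: {directory: path}`` points at the four interface
CSVs instead of a generator block.  ``run_pipeline`` writes every analysis
artifact (curves, summaries, accounting, removal report, run log) under
``output_dir``; figures are rendered separately by :mod:`inhalerhr.report`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import events as ev
from . import group as grp
from . import preprocess as pp
from .store import CohortBundle, read_bundle, write_bundle
from .synth import GeneratorConfig, ParameterError, simulate_cohort

__all__ = ["ConfigError", "DataError", "RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("inhalerhr")


class ConfigError(ValueError):
    """The run configuration is invalid."""


class DataError(RuntimeError):
    """The input data cannot be analysed."""


@dataclass
class EventStudyParams:
    pre_min: int = 180
    post_min: int = 600
    controls_per_side: int = 50
    min_control_days: int = 10
    threshold_bpm: float = 5.0
    step_filter: bool = True
    span: float = 0.15
    refractory_min: int | None = None


@dataclass
class RunConfig:
    output_dir: str = "out"
    seed: int = 0
    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    wear_threshold_min: int = pp.DEFAULT_WEAR_THRESHOLD_MIN
    event_study: EventStudyParams = field(default_factory=EventStudyParams)
    n_boot: int = 200
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ConfigError("exactly one of generator / input_dir must be set")
        if self.wear_threshold_min < 0:
            raise ConfigError("wear_threshold_min must be >= 0")
        es = self.event_study
        if es.pre_min < 0 or es.post_min < 0:
            raise ConfigError("event window extents must be >= 0")
        if not (0 < es.span <= 1):
            raise ConfigError("smoothing span must be in (0, 1]")
        if es.threshold_bpm <= 0:
            raise ConfigError("threshold_bpm must be > 0")
        if es.controls_per_side < 1 or es.min_control_days < 1:
            raise ConfigError("control-day parameters must be >= 1")


def load_config(path) -> RunConfig:
    """Parse a YAML run config; generator parameters are validated eagerly."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        gen = raw.pop("generator", None)
        seed = int(raw.get("seed", 0))
        if gen is not None:
            gen.setdefault("rng_seed", seed)
            gen = GeneratorConfig.from_dict(gen)
        es = EventStudyParams(**raw.pop("event_study", {}))
        inputs = raw.pop("inputs", None)
        input_dir = inputs.get("directory") if inputs else None
        return RunConfig(
            output_dir=raw.get("output_dir", "out"),
            seed=seed,
            generator=gen,
            input_dir=input_dir,
            wear_threshold_min=int(raw.get("wear_threshold_min", pp.DEFAULT_WEAR_THRESHOLD_MIN)),
            event_study=es,
            n_boot=int(raw.get("n_boot", 200)),
            log_level=str(raw.get("log_level", "INFO")),
        )
    except (TypeError, ValueError, ParameterError) as exc:
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc


def _obtain_bundle(config: RunConfig, outdir: Path) -> CohortBundle:
    if config.generator is not None:
        log.info(
            "generating synthetic cohort: %d patients x %d days (seed %d)",
            config.generator.n_patients,
            config.generator.days_per_patient,
            config.generator.rng_seed,
        )
        bundle = simulate_cohort(config.generator)
        write_bundle(bundle, outdir / "data")
        return bundle
    log.info("reading cohort from %s", config.input_dir)
    try:
        return read_bundle(config.input_dir)
    except (OSError, ValueError) as exc:
        raise DataError(f"reading inputs from {config.input_dir}: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a summary dict and writes artifacts.

    Deterministic given config + seed.  Every patient- and event-level
    exclusion is recorded (removal report CSV, event accounting CSV, log).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level.upper())
    summary: dict = {"seed": config.seed}
    try:
        bundle = _obtain_bundle(config, outdir)

        # --- wear accounting and low-wear exclusion
        kept, removal = pp.filter_low_wear(bundle, config.wear_threshold_min)
        removal.to_csv(outdir / "removal_report.csv", index=False)
        log.info(
            "wear filter: kept %d / %d patients (threshold %d min)",
            len(kept), len(bundle), config.wear_threshold_min,
        )
        for _, row in removal[removal.removed].iterrows():
            log.debug("removed %s: %s", row.patient_id, row.reason)
        summary["patients_total"] = len(bundle)
        summary["patients_kept"] = len(kept)
        if len(kept) == 0:
            raise DataError("wear filter removed every patient")

        # --- group comparison
        segments = pp.split_laba_person_time(kept)
        profiles = [pp.hourly_patient_means(s) for s in segments if len(s.hr)]
        try:
            curve = grp.hourly_group_curve(profiles)
            diff = grp.overall_group_difference(
                profiles, segments, n_boot=config.n_boot, seed=config.seed
            )
            curve.table.to_csv(outdir / "hourly_group_curve.csv")
            (outdir / "group_difference.json").write_text(
                json.dumps(diff.to_dict(), indent=2)
            )
            summary["group_difference_bpm"] = diff.difference
            log.info("group difference: %.3f bpm (patient-first)", diff.difference)
        except grp.AnalysisError as exc:
            summary["group_difference_bpm"] = None
            log.warning("group comparison skipped: %s", exc)

        # --- event studies
        es = config.event_study
        window = ev.EventWindow(es.pre_min, es.post_min)
        for label, inhaler in (("saba", "SABA"), ("laba", "LABA")):
            try:
                curve_ev = ev.event_difference_curve(
                    kept,
                    inhaler_type=inhaler,
                    window=window,
                    step_filter=es.step_filter,
                    controls_per_side=es.controls_per_side,
                    min_control_days=es.min_control_days,
                    refractory_min=es.refractory_min,
                )
            except grp.AnalysisError as exc:
                log.warning("%s event study skipped: %s", inhaler, exc)
                summary[f"{label}_events"] = None
                continue
            name = f"{label}_difference_curve.csv"
            curve_ev.table.to_csv(outdir / name, index=False)
            acct = curve_ev.accounting
            summary[f"{label}_events"] = acct.to_dict()
            log.info("%s events: %s", inhaler, acct.to_dict())
            if inhaler == "SABA":
                xs = ev.crossing_summary(curve_ev, es.threshold_bpm)
                (outdir / "saba_crossings.json").write_text(
                    json.dumps(xs.to_dict(), indent=2)
                )
                summary["saba_crossings"] = xs.to_dict()
                try:
                    smoothed = ev.smooth_curve(curve_ev, es.span)
                    smoothed.rename_axis("relative_minute").to_csv(
                        outdir / "saba_smoothed.csv"
                    )
                except grp.AnalysisError as exc:
                    log.warning("smoothing skipped: %s", exc)
                pd.DataFrame([acct.to_dict()]).to_csv(
                    outdir / "event_accounting.csv", index=False
                )
                # steps around events for the activity figure
                try:
                    steps_curve = ev.event_difference_curve(
                        kept, "SABA", window=window, step_filter=False,
                        min_control_days=es.min_control_days, value="steps",
                    )
                    steps_curve.table.to_csv(
                        outdir / "saba_steps_curve.csv", index=False
                    )
                except grp.AnalysisError as exc:
                    log.warning("steps-around-event curve skipped: %s", exc)

        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        log.info("run complete: %s", outdir)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
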