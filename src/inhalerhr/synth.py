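"""Synthetic wearable-cohort generator.

Emulates the data-generating structure the analysis pipeline assumes, so
every stage is testable without access to patient data:

* a single-harmonic circadian (cosinor) heart-rate rhythm;
* an acute beta-2 agonist heart-rate kernel with a linear pre/post-actuation
  rise and an exponential decay anchored at a clinical-relevance threshold;
* as-needed reliever (SABA) use with a morning-skewed diurnal intensity and
  optional coupling to physical-activity bouts (reliever taken around
  exercise);
* twice-daily maintenance-inhaler schedules with imperfect adherence;
* step-count bouts that raise heart rate through a smoothed-step gain, which
  is exactly the confounding the event study's step filter must remove;
* non-wear: occasional daytime charging gaps and reduced nighttime wear.

Everything is deterministic given ``rng_seed``: per-patient generators are
spawned from a single :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .store import (
    HEART_RATE,
    STEPS,
    MINUTES_PER_DAY,
    CohortBundle,
    EventLog,
    MedStatusTimeline,
    MinuteSeries,
    PatientData,
)

__all__ = [
    "ParameterError",
    "DrugEffectKernel",
    "saba_landmark_kernel",
    "build_kernel",
    "night_retention_for_fraction",
    "morning_peak_offset_profile",
    "CircadianParams",
    "ActivityConfig",
    "SabaUseConfig",
    "MaintenanceSchedule",
    "WearConfig",
    "GeneratorConfig",
    "simulate_patient",
    "simulate_cohort",
]


class ParameterError(ValueError):
    """A generator/kernel parameter set is infeasible."""


# ---------------------------------------------------------------------------
# Drug-effect kernel


@dataclass(frozen=True)
class DrugEffectKernel:
    """Acute heart-rate response around a single actuation, in bpm.

    Piecewise shape on relative minutes t (t = 0 is the actuation minute):

    * 0 for t < -onset_lead_min,
    * linear from (-onset_lead_min, 0) to (0, value_at_t0_bpm),
    * linear from (0, value_at_t0_bpm) to (peak_lag_min, peak_amp_bpm),
    * exponential decay after the peak, with the rate solved so that the
      kernel equals ``threshold_bpm`` exactly at ``return_min``.

    The pre-actuation ramp deliberately lumps dyspnea/arousal and drug
    effect into one curve; minute-level sensor data cannot separate them.
    """

    onset_lead_min: float = 38.25
    peak_lag_min: float = 9.0
    peak_amp_bpm: float = 10.0
    value_at_t0_bpm: float = 9.0
    return_min: float = 138.0
    threshold_bpm: float = 5.0

    def __post_init__(self) -> None:
        if not (self.onset_lead_min > 0 < self.peak_lag_min < self.return_min):
            raise ParameterError(
                "need -onset_lead < 0 < peak_lag < return_min "
                f"(got onset {self.onset_lead_min}, peak {self.peak_lag_min}, "
                f"return {self.return_min})"
            )
        if not (0 < self.value_at_t0_bpm <= self.peak_amp_bpm):
            raise ParameterError(
                f"value_at_t0 ({self.value_at_t0_bpm}) must be in (0, peak_amp "
                f"{self.peak_amp_bpm}]"
            )
        if not (0 < self.threshold_bpm < self.peak_amp_bpm):
            raise ParameterError(
                f"threshold ({self.threshold_bpm}) must be in (0, peak_amp)"
            )

    @classmethod
    def from_crossing_landmarks(
        cls,
        first_exceed_pre_min: float = 17.0,
        value_at_t0_bpm: float = 9.0,
        peak_lag_min: float = 9.0,
        peak_amp_bpm: float = 10.0,
        return_min: float = 138.0,
        threshold_bpm: float = 5.0,
    ) -> "DrugEffectKernel":
        """Build a kernel from threshold-crossing landmarks.

        ``first_exceed_pre_min`` is the number of minutes *before* actuation
        at which the curve first reaches ``threshold_bpm`` — the quantity a
        crossing summary reports.  The ramp start (where the kernel is zero)
        is derived by extending the pre-actuation line through
        (-first_exceed_pre, threshold) and (0, value_at_t0) back to zero.
        """
        if value_at_t0_bpm <= threshold_bpm:
            raise ParameterError(
                "value_at_t0 must exceed threshold for a pre-actuation crossing"
            )
        slope = (value_at_t0_bpm - threshold_bpm) / first_exceed_pre_min
        onset = first_exceed_pre_min + threshold_bpm / slope
        return cls(
            onset_lead_min=onset,
            peak_lag_min=peak_lag_min,
            peak_amp_bpm=peak_amp_bpm,
            value_at_t0_bpm=value_at_t0_bpm,
            return_min=return_min,
            threshold_bpm=threshold_bpm,
        )

    @property
    def decay_rate(self) -> float:
        """Exponential decay rate (per minute) after the peak."""
        return math.log(self.peak_amp_bpm / self.threshold_bpm) / (
            self.return_min - self.peak_lag_min
        )

    def __call__(self, t) -> np.ndarray:
        """Evaluate the kernel at relative minutes ``t`` (vectorized)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        rise1 = (t >= -self.onset_lead_min) & (t < 0)
        out[rise1] = self.value_at_t0_bpm * (t[rise1] + self.onset_lead_min) / self.onset_lead_min
        rise2 = (t >= 0) & (t <= self.peak_lag_min)
        out[rise2] = self.value_at_t0_bpm + (
            self.peak_amp_bpm - self.value_at_t0_bpm
        ) * t[rise2] / self.peak_lag_min
        decay = t > self.peak_lag_min
        out[decay] = self.peak_amp_bpm * np.exp(-self.decay_rate * (t[decay] - self.peak_lag_min))
        return out

    def support_grid(self, floor_bpm: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
        """Integer-minute grid covering the kernel down to ``floor_bpm``."""
        t_min = -int(math.ceil(self.onset_lead_min))
        t_max = int(
            math.ceil(
                self.peak_lag_min + math.log(self.peak_amp_bpm / floor_bpm) / self.decay_rate
            )
        )
        t = np.arange(t_min, t_max + 1)
        return t, self(t)


def saba_landmark_kernel() -> DrugEffectKernel:
    """Default reliever kernel: 5-bpm crossing 17 min pre-actuation, 9 bpm at
    the actuation minute, 10 bpm peak 9 min post, back to 5 bpm at 138 min."""
    return DrugEffectKernel.from_crossing_landmarks()


def build_kernel(
    kernel: DrugEffectKernel,
    t_min: int = -180,
    t_max: int = 600,
) -> pd.Series:
    """Evaluate a kernel on a relative-minute grid (returned as a Series)."""
    t = np.arange(int(t_min), int(t_max) + 1)
    return pd.Series(kernel(t), index=t, name="kernel_bpm")


# ---------------------------------------------------------------------------
# Night-wear calibration

_NIGHT_MINUTES = 360.0  # 00:00-06:00
_DAY_MINUTES = float(MINUTES_PER_DAY) - _NIGHT_MINUTES


def night_retention_for_fraction(target_fraction: float, day_retention: float = 1.0) -> float:
    """Night wear probability giving a target share of minutes in 00:00-06:00.

    Solves ``360 p / (360 p + 1080 d) = f`` for ``p``, i.e.
    ``p = 3 d f / (1 - f)``.  With full daytime wear (d = 1) the share is
    capped at 25% (uniform wear), so targets at or above that are infeasible.
    """
    if not (0 < target_fraction < 1):
        raise ParameterError(f"target_fraction must be in (0, 1), got {target_fraction}")
    if not (0 < day_retention <= 1):
        raise ParameterError(f"day_retention must be in (0, 1], got {day_retention}")
    p = (_DAY_MINUTES / _NIGHT_MINUTES) * day_retention * target_fraction / (1 - target_fraction)
    if p > 1:
        raise ParameterError(
            f"night share {target_fraction} infeasible with day retention {day_retention}"
        )
    return p


def morning_peak_offset_profile(
    peak_bpm: float = 3.0, peak_hour: int = 10, sd_hours: float = 2.5
) -> np.ndarray:
    """Hour-of-day LABA offset profile with a Gaussian morning peak (bpm)."""
    hours = np.arange(24)
    return peak_bpm * np.exp(-((hours - peak_hour) ** 2) / (2 * sd_hours**2))


# ---------------------------------------------------------------------------
# Generator configuration


@dataclass(frozen=True)
class CircadianParams:
    """Cosinor heart-rate rhythm: mesor + amplitude * cos(peak at acrophase)."""

    mesor_bpm: float = 70.0
    amplitude_bpm: float = 5.0
    acrophase_min: int = 900  # 3 PM daytime plateau

    def curve(self, minute_of_day) -> np.ndarray:
        m = np.asarray(minute_of_day, dtype=float)
        return self.mesor_bpm + self.amplitude_bpm * np.cos(
            2 * np.pi * (m - self.acrophase_min) / MINUTES_PER_DAY
        )


@dataclass(frozen=True)
class ActivityConfig:
    """Step-bout process and its heart-rate coupling.

    Bouts start uniformly in the daytime window, last a lognormal number of
    minutes, and emit Poisson steps per minute around a per-bout intensity.
    Heart rate rises linearly with the trailing moving average of steps.
    """

    bout_rate_per_day: float = 3.0
    bout_window_min: tuple[int, int] = (480, 1320)  # 8 AM - 10 PM
    bout_duration_median_min: float = 15.0
    bout_duration_sigma: float = 0.6
    intensity_steps_per_min: tuple[float, float] = (40.0, 100.0)
    hr_gain_bpm_per_step_rate: float = 0.2
    smoothing_window_min: int = 10


@dataclass(frozen=True)
class SabaUseConfig:
    """As-needed reliever use.

    Reliever actuations arrive through two day types, reflecting how
    patients actually use them:

    * *lone-event days*: one spontaneous (dyspnea-driven) actuation at a
      time drawn from a diurnal intensity with an 8 AM bump;
    * *exercise days*: a burst of ``events_per_exercise_day`` actuations on
      average (1 + Poisson), all taken around a physical-activity bout —
      these are exactly the events the step filter is meant to remove.

    Day-type probabilities are solved from ``rate_per_day`` (overall mean
    actuations per day) and the cohort's exercise-coupling fraction, so the
    share of actuations with an overlapping bout equals
    ``exercise_coupling_prob`` in expectation.
    """

    rate_per_day: float = 0.36
    events_per_exercise_day: float = 2.0
    event_spread_min: int = 60
    waking_window_min: tuple[int, int] = (360, 1380)  # 6 AM - 11 PM
    morning_peak_min: int = 480
    morning_peak_sd_min: float = 45.0
    morning_peak_weight: float = 0.3

    def day_type_probs(self, coupling_prob: float) -> tuple[float, float]:
        """(P(lone-event day), P(exercise day)) for a given coupled share."""
        p_lone = self.rate_per_day * (1 - coupling_prob)
        p_ex = (
            self.rate_per_day * coupling_prob / self.events_per_exercise_day
            if coupling_prob > 0
            else 0.0
        )
        if p_lone + p_ex > 1:
            raise ParameterError(
                f"reliever rate {self.rate_per_day}/day with coupling "
                f"{coupling_prob} needs day probabilities summing to "
                f"{p_lone + p_ex:.3f} > 1"
            )
        return p_lone, p_ex

    def minute_pmf(self) -> np.ndarray:
        minutes = np.arange(MINUTES_PER_DAY, dtype=float)
        lo, hi = self.waking_window_min
        base = ((minutes >= lo) & (minutes < hi)).astype(float)
        bump = np.exp(-((minutes - self.morning_peak_min) ** 2) / (2 * self.morning_peak_sd_min**2))
        pmf = (1 - self.morning_peak_weight) * base / base.sum()
        pmf = pmf + self.morning_peak_weight * bump / bump.sum()
        return pmf / pmf.sum()


@dataclass(frozen=True)
class MaintenanceSchedule:
    """Twice-daily maintenance inhaler (ICS, or ICS/LABA for LABA users)."""

    morning_min: int = 480
    evening_min: int = 1260
    jitter_sd_min: float = 30.0
    adherence_morning: float = 0.84
    adherence_evening: float = 0.84


@dataclass(frozen=True)
class WearConfig:
    """Non-wear model: daytime charging gaps plus reduced night wear.

    Night minutes (00:00-06:00) are kept in independent hourly blocks with
    probability ``night_retention``; daytime hourly blocks with probability
    ``day_retention``. Charging gaps remove one contiguous daytime run on a
    random subset of days.
    """

    day_retention: float = 1.0
    night_retention: float = 0.690  # ≈ night_retention_for_fraction(0.187)
    charge_gap_prob_per_day: float = 0.3
    charge_gap_duration_min: tuple[int, int] = (60, 180)
    charge_gap_window_min: tuple[int, int] = (420, 1380)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full cohort-generator configuration.

    ``laba_offset_bpm`` is either a scalar (constant heart-rate elevation
    while on LABA) or a 24-vector giving the offset per clock hour.
    """

    n_patients: int = 20
    days_per_patient: int = 60
    start_date: str = "2016-01-01"
    circadian: CircadianParams = field(default_factory=CircadianParams)
    hr_noise_sd: float = 6.0
    laba_offset_bpm: float | tuple = 0.8
    laba_fraction: float = 0.7
    laba_switch_prob: float = 0.0
    saba_kernel: DrugEffectKernel | None = field(default_factory=saba_landmark_kernel)
    laba_acute_kernel: DrugEffectKernel | None = None
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    exercise_coupling_prob: float = 0.5
    saba: SabaUseConfig = field(default_factory=SabaUseConfig)
    maintenance: MaintenanceSchedule = field(default_factory=MaintenanceSchedule)
    wear: WearConfig = field(default_factory=WearConfig)
    clip_bpm: tuple[float, float] = (35.0, 220.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "laba_fraction": self.laba_fraction,
            "laba_switch_prob": self.laba_switch_prob,
            "exercise_coupling_prob": self.exercise_coupling_prob,
            "day_retention": self.wear.day_retention,
            "night_retention": self.wear.night_retention,
            "charge_gap_prob_per_day": self.wear.charge_gap_prob_per_day,
            "adherence_morning": self.maintenance.adherence_morning,
            "adherence_evening": self.maintenance.adherence_evening,
        }
        for name, p in probs.items():
            if not (0 <= p <= 1):
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        if self.hr_noise_sd < 0:
            raise ParameterError("hr_noise_sd must be >= 0")
        if self.n_patients < 0 or self.days_per_patient <= 0:
            raise ParameterError("need n_patients >= 0 and days_per_patient > 0")
        offsets = self.offset_by_hour()
        if offsets.shape != (24,):
            raise ParameterError("laba_offset_bpm must be scalar or length-24")

    def offset_by_hour(self) -> np.ndarray:
        if np.isscalar(self.laba_offset_bpm):
            return np.full(24, float(self.laba_offset_bpm))
        return np.asarray(self.laba_offset_bpm, dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        if not np.isscalar(d["laba_offset_bpm"]):
            d["laba_offset_bpm"] = [float(x) for x in np.asarray(d["laba_offset_bpm"])]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key, sub in (
            ("circadian", CircadianParams),
            ("activity", ActivityConfig),
            ("saba", SabaUseConfig),
            ("maintenance", MaintenanceSchedule),
            ("wear", WearConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub_d = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
                }
                d[key] = sub(**sub_d)
        for key in ("saba_kernel", "laba_acute_kernel"):
            if isinstance(d.get(key), dict):
                d[key] = DrugEffectKernel(**d[key])
        if isinstance(d.get("laba_offset_bpm"), list):
            d["laba_offset_bpm"] = tuple(d["laba_offset_bpm"])
        for key in ("clip_bpm",):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Simulation


def _sample_saba_days(
    rng, config: GeneratorConfig, n_days: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Sample reliever actuations; returns (lone events, coupled events).

    Lone events occur one per lone-event day at a diurnally weighted
    minute; coupled events come in a same-day burst taken around one
    exercise bout.
    """
    saba = config.saba
    p_lone, p_ex = saba.day_type_probs(config.exercise_coupling_prob)
    pmf = saba.minute_pmf()
    u = rng.random(n_days)
    lone: list[tuple[int, int]] = []
    coupled: list[tuple[int, int]] = []
    for day in range(n_days):
        if u[day] < p_ex:
            k = 1 + int(rng.poisson(saba.events_per_exercise_day - 1))
            anchor = int(rng.choice(MINUTES_PER_DAY, p=pmf))
            offsets = np.sort(rng.integers(0, saba.event_spread_min + 1, size=k))
            minutes = sorted({int(np.clip(anchor + o, 0, MINUTES_PER_DAY - 1)) for o in offsets})
            coupled.extend((day, m) for m in minutes)
        elif u[day] < p_ex + p_lone:
            lone.append((day, int(rng.choice(MINUTES_PER_DAY, p=pmf))))
    return lone, coupled


def _add_bout(steps, rng, start: int, duration: int, intensity: float) -> None:
    lo = max(0, start)
    hi = min(len(steps), start + duration)
    if hi > lo:
        steps[lo:hi] += rng.poisson(intensity, size=hi - lo)


def _wear_mask(rng, config: GeneratorConfig, n_days: int) -> np.ndarray:
    wear = config.wear
    n_min = n_days * MINUTES_PER_DAY
    # hourly wear blocks: prob depends on night (hours 0-5) vs day
    block_p = np.where(np.arange(24) < 6, wear.night_retention, wear.day_retention)
    keep_blocks = rng.random(size=(n_days, 24)) < block_p[None, :]
    mask = np.repeat(keep_blocks.reshape(-1), 60)
    # charging gaps: one contiguous daytime run on a random subset of days
    gap_days = rng.random(n_days) < wear.charge_gap_prob_per_day
    for day in np.flatnonzero(gap_days):
        dur = int(rng.integers(*wear.charge_gap_duration_min, endpoint=True))
        lo, hi = wear.charge_gap_window_min
        start = int(rng.integers(lo, hi))
        a = day * MINUTES_PER_DAY + start
        mask[a : min(a + dur, n_min)] = False
    return mask


def _laba_day_flags(
    rng, config: GeneratorConfig, laba_user: bool, n_days: int
) -> np.ndarray:
    """Per-day LABA status; a configurable chance of one mid-follow-up switch."""
    flags = np.full(n_days, laba_user)
    if config.laba_switch_prob > 0 and rng.random() < config.laba_switch_prob:
        switch_day = int(rng.integers(n_days // 4, 3 * n_days // 4 + 1))
        flags[switch_day:] = not laba_user
    return flags


def _timeline_from_flags(patient_id: str, start: pd.Timestamp, flags: np.ndarray) -> MedStatusTimeline:
    rows = []
    run_start = 0
    for day in range(1, len(flags) + 1):
        if day == len(flags) or flags[day] != flags[run_start]:
            rows.append(
                {
                    "start_date": start + pd.Timedelta(days=run_start),
                    "end_date": start + pd.Timedelta(days=day - 1),
                    "laba": bool(flags[run_start]),
                }
            )
            run_start = day
    return MedStatusTimeline(patient_id, pd.DataFrame(rows))


def simulate_patient(
    config: GeneratorConfig, patient_id: str, laba_user: bool, seed
) -> PatientData:
    """Simulate one patient's heart-rate/steps/event/status streams.

    Worn-minute heart rate is
    ``circadian + laba_offset·1[on LABA] + Σ active kernels +
    gain·smoothed_steps + N(0, noise_sd)``, clipped to the physiological
    band; the wear mask is applied last and removes rows rather than
    zero-filling them.
    """
    rng = np.random.default_rng(seed)
    n_days = config.days_per_patient
    n_min = n_days * MINUTES_PER_DAY
    start = pd.Timestamp(config.start_date)

    laba_flags = _laba_day_flags(rng, config, laba_user, n_days)

    # --- reliever events and activity bouts
    lone_events, coupled_events = _sample_saba_days(rng, config, n_days)
    saba_events = sorted(lone_events + coupled_events)
    steps = np.zeros(n_min, dtype=np.int64)
    act = config.activity
    # exercise around coupled reliever use: steps rise ~30 min before the
    # first actuation of the burst to ~90 min after the last
    by_day: dict[int, list[int]] = {}
    for day, minute in coupled_events:
        by_day.setdefault(day, []).append(minute)
    for day, minutes in sorted(by_day.items()):
        intensity = rng.uniform(*act.intensity_steps_per_min)
        start_min = day * MINUTES_PER_DAY + min(minutes) - 30
        duration = (max(minutes) - min(minutes)) + 120
        _add_bout(steps, rng, start_min, duration, intensity)
    bout_counts = rng.poisson(act.bout_rate_per_day, size=n_days)
    for day in range(n_days):
        for _ in range(int(bout_counts[day])):
            start_min = int(rng.integers(*act.bout_window_min))
            duration = max(3, int(round(rng.lognormal(
                math.log(act.bout_duration_median_min), act.bout_duration_sigma
            ))))
            intensity = rng.uniform(*act.intensity_steps_per_min)
            _add_bout(steps, rng, day * MINUTES_PER_DAY + start_min, duration, intensity)

    # --- maintenance inhaler events
    sched = config.maintenance
    maint_events: list[tuple[int, int]] = []
    for day in range(n_days):
        for base, adher in (
            (sched.morning_min, sched.adherence_morning),
            (sched.evening_min, sched.adherence_evening),
        ):
            take = rng.random() < adher
            minute = int(np.clip(round(rng.normal(base, sched.jitter_sd_min)), 0, MINUTES_PER_DAY - 1))
            if take:
                maint_events.append((day, minute))

    # --- heart-rate construction
    minute_of_day = np.tile(np.arange(MINUTES_PER_DAY), n_days)
    hr = config.circadian.curve(minute_of_day)

    offsets = config.offset_by_hour()
    day_flags_by_min = np.repeat(laba_flags, MINUTES_PER_DAY)
    hr = hr + np.where(day_flags_by_min, offsets[minute_of_day // 60], 0.0)

    def add_kernel(kernel: DrugEffectKernel, abs_minute: int) -> None:
        t, vals = kern_grids[id(kernel)]
        lo = abs_minute + int(t[0])
        hi = abs_minute + int(t[-1]) + 1
        s = max(0, lo)
        e = min(n_min, hi)
        if e > s:
            hr[s:e] += vals[s - lo : e - lo]

    kern_grids = {}
    for kernel in (config.saba_kernel, config.laba_acute_kernel):
        if kernel is not None:
            kern_grids[id(kernel)] = kernel.support_grid()
    if config.saba_kernel is not None:
        for day, minute in saba_events:
            add_kernel(config.saba_kernel, day * MINUTES_PER_DAY + minute)
    if config.laba_acute_kernel is not None:
        for day, minute in maint_events:
            if laba_flags[day]:
                add_kernel(config.laba_acute_kernel, day * MINUTES_PER_DAY + minute)

    if act.hr_gain_bpm_per_step_rate:
        w = act.smoothing_window_min
        smoothed = np.convolve(steps, np.ones(w) / w, mode="full")[:n_min]
        hr = hr + act.hr_gain_bpm_per_step_rate * smoothed

    if config.hr_noise_sd > 0:
        hr = hr + rng.normal(0.0, config.hr_noise_sd, size=n_min)
    hr = np.clip(hr, *config.clip_bpm)

    worn = _wear_mask(rng, config, n_days)

    idx_all = start + pd.to_timedelta(np.arange(n_min), unit="m")
    worn_idx = idx_all[worn]
    hr_series = MinuteSeries(patient_id, HEART_RATE, pd.Series(hr[worn], index=worn_idx))
    steps_series = MinuteSeries(
        patient_id, STEPS, pd.Series(steps[worn].astype(float), index=worn_idx)
    )

    ev_rows = [
        {"timestamp": start + pd.Timedelta(minutes=d * MINUTES_PER_DAY + m), "inhaler_type": "SABA"}
        for d, m in saba_events
    ] + [
        {
            "timestamp": start + pd.Timedelta(minutes=d * MINUTES_PER_DAY + m),
            "inhaler_type": "ICS_LABA" if laba_flags[d] else "ICS",
        }
        for d, m in maint_events
    ]
    events = EventLog(
        patient_id,
        pd.DataFrame(ev_rows, columns=["timestamp", "inhaler_type"]),
    )
    timeline = _timeline_from_flags(patient_id, start, laba_flags)
    return PatientData(patient_id, hr_series, steps_series, events, timeline)


def simulate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Simulate a full cohort; deterministic given ``config.rng_seed``.

    A ``laba_fraction`` share of patients (rounded) are LABA users over
    their whole follow-up (subject to ``laba_switch_prob``); assignment and
    per-patient noise streams derive from independent spawned seeds.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    children = ss.spawn(config.n_patients + 1)
    assign_rng = np.random.default_rng(children[0])
    n_laba = int(round(config.laba_fraction * config.n_patients))
    flags = np.zeros(config.n_patients, dtype=bool)
    flags[:n_laba] = True
    assign_rng.shuffle(flags)

    bundle = CohortBundle()
    width = max(3, len(str(max(config.n_patients, 1))))
    for i in range(config.n_patients):
        pid = f"p{i + 1:0{width}d}"
        bundle.patients[pid] = simulate_patient(config, pid, bool(flags[i]), children[i + 1])
    return bundle
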