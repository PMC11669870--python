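"""Self-controlled event study around inhaler actuations.

For each reliever (SABA) actuation the heart rate in the 180 minutes before
to 600 minutes after the actuation is compared against the *same clock
minutes* on up to 100 control days — the nearest 50 earlier and 50 later
calendar days on which that patient recorded no SABA use.  Matching on
clock time cancels the circadian rhythm; matching within patient cancels
stable between-person differences.

Because relievers are often taken around exercise, an event is dropped when
the steps taken from 1 hour before to 1 hour after the actuation exceed the
patient's own control-day mean + 2 SD for the same clock window.

The resulting minute-by-minute difference curve is summarised by its
threshold crossings (first pre-event exceedance, value at the actuation
minute, peak lag and amplitude, and return time), computed on the
*unsmoothed* curve; a locally weighted (tricube, local-linear) smoother is
available for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .store import MINUTES_PER_DAY, CohortBundle, EventLog, MinuteSeries, PatientData
from .group import AnalysisError

__all__ = [
    "EventWindow",
    "ControlSet",
    "StepFilterDecision",
    "DifferenceCurve",
    "CrossingSummary",
    "EventAccounting",
    "select_control_days",
    "control_reference",
    "step_activity_filter",
    "event_difference_curve",
    "crossing_summary",
    "smooth_curve",
]

DEFAULT_THRESHOLD_BPM = 5.0
DEFAULT_MIN_CONTROL_DAYS = 10
CONTROLS_PER_SIDE = 50
STEP_WINDOW_MIN = 60  # +/- 1 hour around the actuation


@dataclass(frozen=True)
class EventWindow:
    """Relative-minute grid around an actuation (minute 0 = actuation)."""

    pre_min: int = 180
    post_min: int = 600

    def __post_init__(self) -> None:
        if self.pre_min < 0 or self.post_min < 0:
            raise ValueError("window extents must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(-self.pre_min, self.post_min + 1)

    def __len__(self) -> int:
        return self.pre_min + self.post_min + 1


@dataclass(frozen=True)
class ControlSet:
    """Matched control days for one actuation: nearest SABA-free worn days,
    capped per side (no topping-up when one side is short)."""

    patient_id: str
    event_date: pd.Timestamp
    prior_dates: tuple
    subsequent_dates: tuple

    @property
    def dates(self) -> tuple:
        return self.prior_dates + self.subsequent_dates

    def __len__(self) -> int:
        return len(self.prior_dates) + len(self.subsequent_dates)


def _split_nearest(eligible_sorted: np.ndarray, pivot, per_side: int):
    """Nearest `per_side` entries strictly below / above pivot."""
    k = int(np.searchsorted(eligible_sorted, pivot, side="left"))
    k_hi = int(np.searchsorted(eligible_sorted, pivot, side="right"))
    prior = eligible_sorted[max(0, k - per_side) : k]
    subseq = eligible_sorted[k_hi : k_hi + per_side]
    return prior, subseq


def _eligible_control_dates(
    events: EventLog, hr: MinuteSeries, control_free_type: str
) -> pd.DatetimeIndex:
    saba_dates = pd.DatetimeIndex(
        events.of_type(control_free_type)["timestamp"]
    ).normalize().unique()
    worn = hr.dates()
    return worn[~worn.isin(saba_dates)]


def select_control_days(
    events: EventLog,
    hr: MinuteSeries,
    event_date,
    controls_per_side: int = CONTROLS_PER_SIDE,
    control_free_type: str = "SABA",
) -> ControlSet:
    """Choose up to ``controls_per_side`` nearest SABA-free days per side.

    Eligible days are calendar dates with at least one worn heart-rate
    minute and zero actuations of ``control_free_type`` by this patient;
    the event date itself is never eligible.
    """
    event_date = pd.Timestamp(event_date).normalize()
    eligible = _eligible_control_dates(events, hr, control_free_type)
    eligible = eligible[eligible != event_date]
    prior, subseq = _split_nearest(
        eligible.to_numpy(), event_date.to_numpy(), controls_per_side
    )
    return ControlSet(
        hr.patient_id,
        event_date,
        tuple(pd.Timestamp(d) for d in prior),
        tuple(pd.Timestamp(d) for d in subseq),
    )


# ---------------------------------------------------------------------------
# Dense per-patient representation used by the vectorized implementation


class _DensePatient:
    """Per-patient flat minute arrays spanning the worn date range."""

    def __init__(self, patient: PatientData) -> None:
        self.patient_id = patient.patient_id
        hr_idx = patient.hr.data.index
        steps_idx = patient.steps.data.index
        if len(hr_idx) == 0:
            self.empty = True
            return
        self.empty = False
        bounds = [hr_idx[0].normalize(), hr_idx[-1].normalize()]
        if len(steps_idx):
            bounds += [steps_idx[0].normalize(), steps_idx[-1].normalize()]
        start, end = min(bounds), max(bounds)
        self.start = start
        self.n_days = int((end - start).days) + 1
        n_min = self.n_days * MINUTES_PER_DAY

        def positions(idx):
            return (
                (idx.normalize() - start).days.to_numpy() * MINUTES_PER_DAY
                + idx.hour.to_numpy() * 60
                + idx.minute.to_numpy()
            )

        self.hr = np.full(n_min, np.nan)
        self.hr[positions(hr_idx)] = patient.hr.data.to_numpy(dtype=float)
        # steps: 0 where worn but none recorded; wear mask tracked separately
        self.steps = np.zeros(n_min)
        self.steps_worn = np.zeros(n_min)
        if len(steps_idx):
            pos = positions(steps_idx)
            self.steps[pos] = patient.steps.data.to_numpy(dtype=float)
            self.steps_worn[pos] = 1.0
        self.n_min = n_min

    def day_index(self, date) -> int:
        return int((pd.Timestamp(date).normalize() - self.start).days)

    def day_indices(self, dates) -> np.ndarray:
        return np.array([self.day_index(d) for d in dates], dtype=np.int64)


def _gather(flat: np.ndarray, day_indices: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Matrix flat[day*1440 + offset] with out-of-range entries as NaN."""
    pos = day_indices[:, None] * MINUTES_PER_DAY + offsets[None, :]
    valid = (pos >= 0) & (pos < len(flat))
    out = np.full(pos.shape, np.nan)
    out[valid] = flat[pos[valid]]
    return out


def _control_reference_by_days(
    dense: _DensePatient,
    control_days: np.ndarray,
    window: EventWindow,
    event_minute_of_day: int,
    min_control_days: int,
) -> tuple[np.ndarray, np.ndarray]:
    offsets = event_minute_of_day + window.grid
    mat = _gather(dense.hr, control_days, offsets)
    counts = np.sum(~np.isnan(mat), axis=0)
    sums = np.nansum(np.where(np.isnan(mat), 0.0, mat), axis=0)
    means = np.full(len(offsets), np.nan)
    ok = counts >= max(min_control_days, 1)
    means[ok] = sums[ok] / counts[ok]
    return means, counts


def control_reference(
    patient: PatientData,
    control: ControlSet,
    window: EventWindow,
    event_minute_of_day: int,
    min_control_days: int = DEFAULT_MIN_CONTROL_DAYS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-relative-minute mean control heart rate and contributing counts.

    Relative minute r is read at clock minute ``event_minute_of_day + r`` on
    each control date, spilling into the adjacent calendar date when the
    shifted minute crosses midnight.  Minutes covered by fewer than
    ``min_control_days`` control-day values are undefined (NaN).
    """
    if len(control) == 0:
        raise AnalysisError("empty control set")
    dense = _DensePatient(patient)
    return _control_reference_by_days(
        dense, dense.day_indices(control.dates), window, event_minute_of_day,
        min_control_days,
    )


@dataclass(frozen=True)
class StepFilterDecision:
    """Physical-activity screen for one actuation.

    The event is kept iff its +/-1 h step total does not exceed the
    control-day mean + 2 sample SDs for the same clock window (equality
    keeps the event; the exclusion is strict ``>``).
    """

    patient_id: str
    event_date: pd.Timestamp
    event_minute: int
    event_window_steps: float | None
    control_mean: float | None
    control_sd: float | None
    included: bool
    reason: str


def _step_filter_by_days(
    dense: _DensePatient,
    event_day: int,
    event_minute_of_day: int,
    control_days: np.ndarray,
    event_date: pd.Timestamp,
) -> StepFilterDecision:
    offsets = event_minute_of_day + np.arange(-STEP_WINDOW_MIN, STEP_WINDOW_MIN + 1)
    ev_worn = _gather(dense.steps_worn, np.array([event_day]), offsets)[0]
    if not np.nansum(ev_worn) > 0:
        return StepFilterDecision(
            dense.patient_id, event_date, event_minute_of_day, None, None, None,
            False, "no step wear in event window",
        )
    ev_steps = _gather(dense.steps, np.array([event_day]), offsets)[0]
    event_total = float(np.nansum(ev_steps))

    ctl_worn = _gather(dense.steps_worn, control_days, offsets)
    covered = np.nansum(np.where(np.isnan(ctl_worn), 0.0, ctl_worn), axis=1) > 0
    if covered.sum() < 2:
        return StepFilterDecision(
            dense.patient_id, event_date, event_minute_of_day, event_total, None,
            None, False, "fewer than 2 control days with step coverage",
        )
    ctl_steps = _gather(dense.steps, control_days, offsets)
    totals = np.nansum(np.where(np.isnan(ctl_steps), 0.0, ctl_steps), axis=1)[covered]
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1))
    included = event_total <= mean + 2 * sd
    return StepFilterDecision(
        dense.patient_id, event_date, event_minute_of_day, event_total, mean, sd,
        bool(included), "" if included else "steps exceed control mean + 2 SD",
    )


def step_activity_filter(
    patient: PatientData,
    event_date,
    event_minute_of_day: int,
    control: ControlSet,
) -> StepFilterDecision:
    """Decide whether an actuation is contaminated by physical activity.

    Missing step minutes during worn periods count as zero steps; if the
    entire +/-1 h event window has no step wear, or fewer than 2 control
    days cover the window, the event is excluded for lack of wear.
    """
    event_date = pd.Timestamp(event_date).normalize()
    dense = _DensePatient(patient)
    return _step_filter_by_days(
        dense,
        dense.day_index(event_date),
        event_minute_of_day,
        dense.day_indices(control.dates),
        event_date,
    )


@dataclass
class EventAccounting:
    """Exact partition of actuations across inclusion outcomes."""

    total: int = 0
    included: int = 0
    excluded_by_steps: int = 0
    excluded_no_controls: int = 0
    excluded_no_wear: int = 0

    def check(self) -> None:
        assert self.total == (
            self.included
            + self.excluded_by_steps
            + self.excluded_no_controls
            + self.excluded_no_wear
        )

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "included": self.included,
            "excluded_by_steps": self.excluded_by_steps,
            "excluded_no_controls": self.excluded_no_controls,
            "excluded_no_wear": self.excluded_no_wear,
        }


@dataclass
class DifferenceCurve:
    """Minute-by-minute event-vs-control comparison.

    ``table`` columns: relative_minute, event_mean, control_mean,
    difference, n_events, n_control_days.  Minutes failing coverage rules
    are NaN (undefined), never zero.  For analyses run without control-day
    subtraction the control columns and difference are NaN throughout.
    """

    table: pd.DataFrame
    accounting: EventAccounting
    decisions: list[StepFilterDecision] = field(default_factory=list)

    @property
    def difference(self) -> pd.Series:
        return self.table.set_index("relative_minute")["difference"]

    @property
    def event_mean(self) -> pd.Series:
        return self.table.set_index("relative_minute")["event_mean"]


def event_difference_curve(
    bundle: CohortBundle,
    inhaler_type: str = "SABA",
    window: EventWindow | None = None,
    step_filter: bool = True,
    use_controls: bool = True,
    controls_per_side: int = CONTROLS_PER_SIDE,
    min_control_days: int = DEFAULT_MIN_CONTROL_DAYS,
    refractory_min: int | None = None,
    value: str = "hr",
) -> DifferenceCurve:
    """Pooled event-aligned difference curve across the cohort.

    ``inhaler_type='SABA'`` analyses reliever actuations against SABA-free
    control days.  ``inhaler_type='LABA'`` pools LABA and ICS_LABA
    maintenance actuations and (by design) reports the raw event-aligned
    heart rate without control-day subtraction, since no maintenance-free
    control-day definition exists.

    ``value='steps'`` compares step counts instead of heart rate (used for
    the activity-around-inhalation figure); missing step minutes on worn
    days count as zero there.

    ``refractory_min`` optionally drops actuations occurring within that
    many minutes after a previously analysed actuation (off by default:
    every actuation is an event).
    """
    window = window or EventWindow()
    if inhaler_type == "SABA":
        types = ("SABA",)
    elif inhaler_type == "LABA":
        types = ("LABA", "ICS_LABA")
        use_controls = False
    else:
        raise ValueError("inhaler_type must be 'SABA' or 'LABA'")
    if value not in ("hr", "steps"):
        raise ValueError("value must be 'hr' or 'steps'")

    grid = window.grid
    n_grid = len(grid)
    ev_sum = np.zeros(n_grid)
    ev_cnt = np.zeros(n_grid, dtype=np.int64)
    ctl_sum = np.zeros(n_grid)
    ctl_cnt = np.zeros(n_grid, dtype=np.int64)
    ctl_days = np.zeros(n_grid, dtype=np.int64)
    acct = EventAccounting()
    decisions: list[StepFilterDecision] = []

    for patient in bundle:
        ev = patient.events.of_type(*types)
        if len(ev) == 0:
            continue
        dense = _DensePatient(patient)
        if dense.empty:
            acct.total += len(ev)
            acct.excluded_no_wear += len(ev)
            continue
        signal = dense.hr if value == "hr" else np.where(
            dense.steps_worn > 0, dense.steps, np.nan
        )
        eligible = _eligible_control_dates(patient.events, patient.hr, "SABA")
        eligible_days = np.sort(dense.day_indices(eligible))
        last_kept_abs: float = -np.inf
        for ts in pd.DatetimeIndex(ev["timestamp"]):
            acct.total += 1
            date = ts.normalize()
            minute = ts.hour * 60 + ts.minute
            event_day = dense.day_index(date)
            abs_min = event_day * MINUTES_PER_DAY + minute
            if refractory_min is not None and abs_min - last_kept_abs < refractory_min:
                acct.excluded_no_wear += 1  # refractory drop, reported in log
                continue

            ctl_means = None
            if use_controls:
                elig = eligible_days[eligible_days != event_day]
                prior, subseq = _split_nearest(elig, event_day, controls_per_side)
                control_days = np.concatenate([prior, subseq])
                if len(control_days) == 0:
                    acct.excluded_no_controls += 1
                    continue
                if step_filter:
                    decision = _step_filter_by_days(
                        dense, event_day, minute, control_days, date
                    )
                    decisions.append(decision)
                    if not decision.included:
                        if decision.reason == "steps exceed control mean + 2 SD":
                            acct.excluded_by_steps += 1
                        else:
                            acct.excluded_no_wear += 1
                        continue
                mat = _gather(signal, control_days, minute + grid)
                counts = np.sum(~np.isnan(mat), axis=0)
                sums = np.nansum(np.where(np.isnan(mat), 0.0, mat), axis=0)
                ctl_means = np.full(n_grid, np.nan)
                ok = counts >= max(min_control_days, 1)
                ctl_means[ok] = sums[ok] / counts[ok]
                ctl_counts = counts

            ev_vals = _gather(signal, np.array([event_day]), minute + grid)[0]
            acct.included += 1
            last_kept_abs = abs_min
            if ctl_means is not None:
                # paired: a minute contributes only when the event day AND
                # its control reference are both defined, so the same event
                # set underlies both means (self-controlled comparison)
                ok = ~np.isnan(ev_vals) & ~np.isnan(ctl_means)
                ev_sum[ok] += ev_vals[ok]
                ev_cnt[ok] += 1
                ctl_sum[ok] += ctl_means[ok]
                ctl_cnt[ok] += 1
                ctl_days[ok] += ctl_counts[ok]
            else:
                ok = ~np.isnan(ev_vals)
                ev_sum[ok] += ev_vals[ok]
                ev_cnt[ok] += 1

    if acct.included == 0:
        acct.check()
        reasons = {
            "excluded_by_steps": acct.excluded_by_steps,
            "excluded_no_controls": acct.excluded_no_controls,
            "excluded_no_wear": acct.excluded_no_wear,
        }
        dominant = max(reasons, key=reasons.get) if acct.total else "no events"
        raise AnalysisError(
            f"no {inhaler_type} event survives filtering "
            f"(total {acct.total}, dominant reason: {dominant})"
        )

    event_mean = np.where(ev_cnt > 0, ev_sum / np.maximum(ev_cnt, 1), np.nan)
    control_mean = np.where(ctl_cnt > 0, ctl_sum / np.maximum(ctl_cnt, 1), np.nan)
    difference = event_mean - control_mean  # NaN where either side undefined

    table = pd.DataFrame(
        {
            "relative_minute": grid,
            "event_mean": event_mean,
            "control_mean": control_mean,
            "difference": difference,
            "n_events": ev_cnt,
            "n_control_days": ctl_days,
        }
    )
    acct.check()
    return DifferenceCurve(table, acct, decisions)


@dataclass(frozen=True)
class CrossingSummary:
    """Threshold-crossing landmarks of an (unsmoothed) difference curve.

    ``first_exceed_pre`` is the earliest pre-actuation relative minute (< 0)
    at which the difference reaches the threshold; ``return_min`` is one
    minute past the last post-actuation exceedance, i.e. the first minute
    after which no further clinically relevant difference occurs.  Either is
    None when no such exceedance exists.
    """

    threshold_bpm: float
    first_exceed_pre: int | None
    value_at_t0: float
    peak_lag: int
    peak_diff: float
    return_min: int | None

    def to_dict(self) -> dict:
        return {
            "threshold_bpm": self.threshold_bpm,
            "first_exceed_pre": self.first_exceed_pre,
            "value_at_t0": self.value_at_t0,
            "peak_lag": self.peak_lag,
            "peak_diff": self.peak_diff,
            "return_min": self.return_min,
        }


def crossing_summary(
    curve: DifferenceCurve | pd.Series, threshold: float = DEFAULT_THRESHOLD_BPM
) -> CrossingSummary:
    """Landmarks of the unsmoothed difference curve at a bpm threshold."""
    diff = curve.difference if isinstance(curve, DifferenceCurve) else curve
    rel = diff.index.to_numpy()
    vals = diff.to_numpy(dtype=float)
    defined = ~np.isnan(vals)
    at0 = np.flatnonzero(defined & (rel == 0))
    if len(at0) == 0:
        raise AnalysisError("difference curve undefined at the actuation minute")
    value_at_t0 = float(vals[at0[0]])

    pre = defined & (rel < 0) & (vals >= threshold)
    first_exceed_pre = int(rel[np.flatnonzero(pre)[0]]) if pre.any() else None

    peak_idx = int(np.argmax(np.where(defined, vals, -np.inf)))
    peak_lag = int(rel[peak_idx])
    peak_diff = float(vals[peak_idx])

    post = defined & (rel > 0) & (vals >= threshold)
    return_min = int(rel[np.flatnonzero(post)[-1]]) + 1 if post.any() else None

    return CrossingSummary(
        threshold_bpm=float(threshold),
        first_exceed_pre=first_exceed_pre,
        value_at_t0=value_at_t0,
        peak_lag=peak_lag,
        peak_diff=peak_diff,
        return_min=return_min,
    )


def smooth_curve(
    curve: DifferenceCurve | pd.Series, span: float = 0.15
) -> pd.Series:
    """Locally weighted (tricube, local-linear) smooth of the curve.

    ``span`` is the fraction of defined minutes in each local fit.
    Undefined minutes are skipped, never interpolated into existence; the
    smoothed series is indexed by the defined relative minutes only.
    """
    diff = curve.difference if isinstance(curve, DifferenceCurve) else curve
    diff = diff.dropna()
    if len(diff) * span < 2 or len(diff) < 4:
        raise AnalysisError(f"too few defined minutes ({len(diff)}) for span {span}")
    smoothed = lowess(
        diff.to_numpy(), diff.index.to_numpy(dtype=float), frac=span, it=0,
        return_sorted=False,
    )
    return pd.Series(smoothed, index=diff.index, name="smoothed")
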