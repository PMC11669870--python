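"""Self-controlled event study: control matching, activity filter,
difference curves, crossings, smoothing."""

import numpy as np
import pandas as pd
import pytest

from inhalerhr.events import (
    ControlSet,
    EventWindow,
    control_reference,
    crossing_summary,
    event_difference_curve,
    select_control_days,
    smooth_curve,
    step_activity_filter,
)
from inhalerhr.group import AnalysisError
from inhalerhr.store import EventLog
from inhalerhr.synth import (
    ActivityConfig,
    CircadianParams,
    GeneratorConfig,
    SabaUseConfig,
    build_kernel,
    saba_landmark_kernel,
    simulate_cohort,
)

from conftest import make_bundle, make_patient
from oracle import oracle_event_study


def saba_log(patient_id, dates, minute=600):
    rows = [
        {"timestamp": pd.Timestamp(d) + pd.Timedelta(minutes=minute), "inhaler_type": "SABA"}
        for d in dates
    ]
    return EventLog(patient_id, pd.DataFrame(rows, columns=["timestamp", "inhaler_type"]))


class TestControlDaySelection:
    def test_daily_user_has_no_control_days(self):
        n = 30
        p = make_patient("p1", n_days=n)
        dates = [pd.Timestamp("2016-01-01") + pd.Timedelta(days=i) for i in range(n)]
        log = saba_log("p1", dates)
        cs = select_control_days(log, p.hr, dates[10])
        assert len(cs) == 0

    def test_per_side_caps_without_topup(self):
        # 30 eligible days before, plenty after: 30 + 50, never topped up
        n = 300
        p = make_patient("p1", n_days=n)
        event_date = pd.Timestamp("2016-01-31")  # day index 30
        log = saba_log("p1", [event_date])
        cs = select_control_days(log, p.hr, event_date)
        assert len(cs.prior_dates) == 30
        assert len(cs.subsequent_dates) == 50
        assert len(cs) == 80

    def test_hundred_nearest_selected(self):
        n = 365
        p = make_patient("p1", n_days=n)
        event_date = pd.Timestamp("2016-01-01") + pd.Timedelta(days=182)
        log = saba_log("p1", [event_date])
        cs = select_control_days(log, p.hr, event_date)
        assert len(cs) == 100
        gaps = [abs((d - event_date).days) for d in cs.dates]
        assert max(gaps) == 50  # the nearest 50 on each side

    def test_event_days_of_other_events_excluded(self):
        p = make_patient("p1", n_days=10)
        d1, d2 = pd.Timestamp("2016-01-03"), pd.Timestamp("2016-01-06")
        log = saba_log("p1", [d1, d2])
        cs = select_control_days(log, p.hr, d1)
        assert d2 not in cs.dates and d1 not in cs.dates
        assert len(cs) == 8


class TestControlReference:
    def test_constant_patient_gives_constant_reference(self):
        p = make_patient("p1", n_days=21)
        event_date = pd.Timestamp("2016-01-11")
        log = saba_log("p1", [event_date])
        cs = select_control_days(log, p.hr, event_date)
        means, counts = control_reference(p, cs, EventWindow(), 600, min_control_days=5)
        defined = ~np.isnan(means)
        assert defined.all()
        assert np.allclose(means[defined], 70.0)

    def test_midnight_spill_reads_next_calendar_day(self):
        # HR encodes the day index: value = 50 + day.  An event at 23:30 with
        # relative minute +120 must read 01:30 of the *next* calendar day.
        p = make_patient("p1", n_days=9, hr_fn=lambda a, m: 50.0 + a // 1440)
        event_date = pd.Timestamp("2016-01-05")  # day index 4
        log = saba_log("p1", [event_date], minute=1410)
        cs = select_control_days(log, p.hr, event_date)
        means, _ = control_reference(p, cs, EventWindow(), 1410, min_control_days=1)
        grid = EventWindow().grid
        # control days are day indices {0..3, 5..8}; at +120 each reads the
        # next day's 01:30 (day 8 spills past the series end and drops out)
        at_plus_120 = means[grid == 120][0]
        assert at_plus_120 == pytest.approx(np.mean([51, 52, 53, 54, 56, 57, 58]))
        at_zero = means[grid == 0][0]
        assert at_zero == pytest.approx(np.mean(50.0 + np.array([0, 1, 2, 3, 5, 6, 7, 8])))

    def test_cosinor_patient_matches_closed_form(self):
        circ = CircadianParams(mesor_bpm=70, amplitude_bpm=5, acrophase_min=900)
        p = make_patient("p1", n_days=15, hr_fn=lambda a, m: float(circ.curve(m)))
        event_date = pd.Timestamp("2016-01-08")
        log = saba_log("p1", [event_date])
        cs = select_control_days(log, p.hr, event_date)
        means, _ = control_reference(p, cs, EventWindow(), 480, min_control_days=1)
        expected = circ.curve((480 + EventWindow().grid) % 1440)
        assert np.allclose(means, expected, atol=1e-9)


class TestStepFilter:
    def _patient_with_window_steps(self, event_total, control_totals, minute=600):
        # event on the last day; control days hold the given window totals,
        # spread uniformly over the 121-minute window
        n_days = len(control_totals) + 1
        steps = np.zeros(n_days * 1440)
        for i, tot in enumerate(control_totals):
            steps[i * 1440 + minute - 60 : i * 1440 + minute + 61] = tot / 121.0
        d_ev = n_days - 1
        steps[d_ev * 1440 + minute - 60 : d_ev * 1440 + minute + 61] = event_total / 121.0
        p = make_patient("p1", n_days=n_days)
        p.steps.data[:] = steps  # same wear mask (all worn)
        event_date = pd.Timestamp("2016-01-01") + pd.Timedelta(days=d_ev)
        ctl = ControlSet(
            "p1",
            event_date,
            tuple(pd.Timestamp("2016-01-01") + pd.Timedelta(days=i) for i in range(d_ev)),
            (),
        )
        return p, event_date, ctl

    def test_zero_steps_everywhere_included(self):
        p, d, ctl = self._patient_with_window_steps(0.0, [0.0, 0.0, 0.0])
        dec = step_activity_filter(p, d, 600, ctl)
        assert dec.included  # 0 <= 0 + 2*0: equality keeps the event

    def test_sd_zero_and_tiny_excess_excluded(self):
        p, d, ctl = self._patient_with_window_steps(101.0, [100.0, 100.0, 100.0])
        dec = step_activity_filter(p, d, 600, ctl)
        assert not dec.included
        assert dec.control_sd == pytest.approx(0.0)

    def test_sample_sd_convention(self):
        # controls {0, 200}: mean 100, sample SD 141.42, bound 382.8 -> 300 kept
        p, d, ctl = self._patient_with_window_steps(300.0, [0.0, 200.0])
        dec = step_activity_filter(p, d, 600, ctl)
        assert dec.included
        assert dec.control_mean == pytest.approx(100.0)
        assert dec.control_sd == pytest.approx(141.4213562, rel=1e-6)

    def test_unworn_event_window_excluded(self):
        p, d, ctl = self._patient_with_window_steps(0.0, [0.0, 0.0])
        worn = np.ones(3 * 1440, bool)
        worn[2 * 1440 + 600 - 60 : 2 * 1440 + 600 + 61] = False
        p2 = make_patient("p1", n_days=3, worn=worn)
        dec = step_activity_filter(p2, d, 600, ctl)
        assert not dec.included and "no step wear" in dec.reason


class TestCrossingSummary:
    def test_flat_zero_curve(self):
        s = pd.Series(0.0, index=np.arange(-180, 601))
        xs = crossing_summary(s)
        assert xs.first_exceed_pre is None
        assert xs.return_min is None
        assert xs.peak_diff == 0.0
        assert xs.value_at_t0 == 0.0

    def test_kernel_curve_recovers_landmarks(self):
        series = build_kernel(saba_landmark_kernel())
        xs = crossing_summary(series, threshold=5.0)
        assert xs.first_exceed_pre == -17
        assert xs.peak_lag == 9
        assert xs.peak_diff == pytest.approx(10.0)
        assert xs.value_at_t0 == pytest.approx(9.0)
        # kernel(138) = 5.0 exactly counts as an exceedance, so the first
        # minute with no further relevant difference is 139
        assert xs.return_min == 139

    def test_undefined_at_t0_is_an_error(self):
        s = pd.Series(np.nan, index=np.arange(-180, 601))
        s.loc[100] = 7.0
        with pytest.raises(AnalysisError):
            crossing_summary(s)


class TestSmoothing:
    def test_constant_curve_reproduced(self):
        s = pd.Series(3.3, index=np.arange(-180, 601))
        sm = smooth_curve(s, span=0.15)
        assert np.allclose(sm.to_numpy(), 3.3, atol=1e-9)

    def test_linear_curve_reproduced(self):
        idx = np.arange(-180, 601)
        s = pd.Series(0.01 * idx + 2, index=idx)
        sm = smooth_curve(s, span=0.2)
        assert np.allclose(sm.to_numpy(), s.to_numpy(), atol=1e-6)

    def test_too_few_points_is_an_error(self):
        s = pd.Series([1.0, 2.0], index=[0, 1])
        with pytest.raises(AnalysisError):
            smooth_curve(s)

    def test_noise_reduction_on_kernel(self):
        # minute-level noise of a few bpm, as in the real difference curve
        kernel = build_kernel(saba_landmark_kernel())
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(50):
            noisy = kernel + rng.normal(0, 3.0, len(kernel))
            sm = smooth_curve(noisy, span=0.15)
            raw_err = np.abs((noisy - kernel).to_numpy()).max()
            sm_err = np.abs((sm - kernel).to_numpy()).max()
            wins += int(sm_err < raw_err)
        assert wins >= 48  # smoothing reduces the worst-case error


class TestEventCurve:
    def test_null_flat_cohort_gives_near_zero_curve(self):
        cfg = GeneratorConfig(
            n_patients=3, days_per_patient=30, saba_kernel=None,
            exercise_coupling_prob=0.0, hr_noise_sd=0.0,
            circadian=CircadianParams(amplitude_bpm=0.0),
            activity=ActivityConfig(bout_rate_per_day=0.0, hr_gain_bpm_per_step_rate=0.0),
            saba=SabaUseConfig(rate_per_day=0.5), rng_seed=1,
        )
        bundle = simulate_cohort(cfg)
        curve = event_difference_curve(bundle, "SABA", min_control_days=3)
        d = curve.difference.dropna()
        assert len(d) > 500
        assert np.abs(d.to_numpy()).max() < 1e-9

    def test_matches_bruteforce_oracle_exactly(self):
        cfg = GeneratorConfig(
            n_patients=3, days_per_patient=10,
            saba=SabaUseConfig(rate_per_day=0.8), rng_seed=6,
        )
        bundle = simulate_cohort(cfg)
        expected, expected_acct = oracle_event_study(
            bundle, per_side=50, min_control_days=2, step_filter=True
        )
        got = event_difference_curve(bundle, "SABA", min_control_days=2)
        assert got.accounting.to_dict() == expected_acct
        np.testing.assert_array_equal(
            got.table["n_events"].to_numpy(), expected["n_events"].to_numpy()
        )
        np.testing.assert_array_equal(
            got.table["n_control_days"].to_numpy(), expected["n_control_days"].to_numpy()
        )
        for col in ("event_mean", "control_mean", "difference"):
            np.testing.assert_allclose(
                got.table[col].to_numpy(), expected[col].to_numpy(),
                rtol=1e-10, atol=1e-10, equal_nan=True,
            )

    def test_accounting_partitions_events(self):
        cfg = GeneratorConfig(
            n_patients=4, days_per_patient=20,
            saba=SabaUseConfig(rate_per_day=0.9), rng_seed=8,
        )
        bundle = simulate_cohort(cfg)
        curve = event_difference_curve(bundle, "SABA", min_control_days=3)
        a = curve.accounting
        assert a.total == sum(
            [a.included, a.excluded_by_steps, a.excluded_no_controls, a.excluded_no_wear]
        )
        assert a.total == sum(len(p.events.of_type("SABA")) for p in bundle)

    def test_all_events_excluded_raises_with_reason(self):
        p = make_patient(
            "p1", n_days=5,
            events=[(d * 1440 + 600, "SABA") for d in range(5)],  # daily user
        )
        with pytest.raises(AnalysisError, match="no_controls"):
            event_difference_curve(make_bundle(p), "SABA")

    def test_laba_mode_pools_maintenance_and_skips_controls(self):
        p = make_patient(
            "p1", n_days=3,
            events=[(480, "LABA"), (1440 + 480, "ICS_LABA"), (2 * 1440 + 480, "ICS")],
        )
        curve = event_difference_curve(make_bundle(p), "LABA", step_filter=False)
        assert curve.accounting.total == 2  # ICS alone is not pooled
        assert curve.table["control_mean"].isna().all()
        assert curve.table["event_mean"].notna().any()

    def test_confounding_removal_by_step_filter(self):
        # zero drug effect but exercise-coupled reliever use: the filtered
        # analysis should show a smaller activity artefact than unfiltered
        wins = 0
        for seed in range(50):
            cfg = GeneratorConfig(
                n_patients=3, days_per_patient=40, saba_kernel=None,
                exercise_coupling_prob=0.5,
                saba=SabaUseConfig(rate_per_day=0.8), rng_seed=seed,
            )
            bundle = simulate_cohort(cfg)
            filt = event_difference_curve(bundle, "SABA", step_filter=True,
                                          min_control_days=3)
            raw = event_difference_curve(bundle, "SABA", step_filter=False,
                                         min_control_days=3)
            peak_f = np.nanmax(np.abs(filt.difference.to_numpy()))
            peak_r = np.nanmax(np.abs(raw.difference.to_numpy()))
            wins += int(peak_f < peak_r)
        assert wins >= 45  # >= 90% of runs

    def test_circadian_phase_invariance(self):
        # shifting the acrophase by 6 h must not move the recovered
        # landmarks: clock-time control matching removes the rhythm
        landmarks = []
        for acro in (900, 540):
            cfg = GeneratorConfig(
                n_patients=8, days_per_patient=80,
                circadian=CircadianParams(acrophase_min=acro),
                saba=SabaUseConfig(rate_per_day=1.0), rng_seed=17,
            )
            bundle = simulate_cohort(cfg)
            curve = event_difference_curve(bundle, "SABA")
            landmarks.append(crossing_summary(curve))
        a, b = landmarks
        assert abs(a.peak_diff - b.peak_diff) < 1.5
        assert abs(a.peak_lag - b.peak_lag) <= 10
        assert abs(a.value_at_t0 - b.value_at_t0) < 1.5
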