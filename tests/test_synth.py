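"""Synthetic-cohort generator: kernel shape, wear calibration, determinism,
and recovery of closed-form expectations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from inhalerhr.synth import (
    ActivityConfig,
    CircadianParams,
    DrugEffectKernel,
    GeneratorConfig,
    ParameterError,
    SabaUseConfig,
    WearConfig,
    build_kernel,
    morning_peak_offset_profile,
    night_retention_for_fraction,
    saba_landmark_kernel,
    simulate_cohort,
)


def quiet_config(**kw):
    """Generator config with every stochastic HR effect switched off."""
    defaults = dict(
        n_patients=1,
        days_per_patient=3,
        circadian=CircadianParams(mesor_bpm=70.0, amplitude_bpm=0.0),
        hr_noise_sd=0.0,
        laba_offset_bpm=0.0,
        laba_fraction=0.0,
        saba_kernel=None,
        activity=ActivityConfig(bout_rate_per_day=0.0, hr_gain_bpm_per_step_rate=0.0),
        exercise_coupling_prob=0.0,
        saba=SabaUseConfig(rate_per_day=0.0),
        wear=WearConfig(night_retention=1.0, charge_gap_prob_per_day=0.0),
        rng_seed=0,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestKernel:
    def test_paper_profile_anchors(self):
        # explicit onset variant: anchors at the peak and the return minute
        k = DrugEffectKernel(onset_lead_min=17.0)
        assert k(np.array([9.0]))[0] == pytest.approx(10.0, abs=1e-12)
        assert k(np.array([138.0]))[0] == pytest.approx(5.0, abs=1e-12)
        assert k(np.array([0.0]))[0] == pytest.approx(9.0, abs=1e-12)

    def test_zero_outside_support(self):
        k = DrugEffectKernel(onset_lead_min=17.0)
        assert k(np.array([-30.0]))[0] == 0.0

    def test_decay_rate_closed_form(self):
        # solve peak_amp * exp(-lam (t - peak_lag)) = threshold at t = return
        k = saba_landmark_kernel()
        assert k.decay_rate == pytest.approx(math.log(10 / 5) / (138 - 9), rel=1e-12)
        assert k.decay_rate == pytest.approx(0.005373, abs=5e-7)

    def test_landmark_constructor_places_crossing(self):
        # the 5-bpm crossing of the rising limb sits 17 min before actuation
        k = saba_landmark_kernel()
        assert k(np.array([-17.0]))[0] == pytest.approx(5.0, abs=1e-12)
        assert k.onset_lead_min == pytest.approx(38.25)
        assert k(np.array([-38.25]))[0] == 0.0

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ParameterError):
            DrugEffectKernel(value_at_t0_bpm=12.0)  # exceeds peak amplitude
        with pytest.raises(ParameterError):
            DrugEffectKernel(threshold_bpm=11.0)
        with pytest.raises(ParameterError):
            DrugEffectKernel(peak_lag_min=200.0, return_min=138.0)

    def test_build_kernel_grid(self):
        series = build_kernel(saba_landmark_kernel())
        assert list(series.index[[0, -1]]) == [-180, 600]
        assert series.loc[9] == pytest.approx(10.0)

    @given(
        onset=st.floats(1, 120),
        peak_lag=st.floats(1, 60),
        amp=st.floats(6, 40),
        frac_t0=st.floats(0.1, 1.0),
        ret=st.floats(61, 500),
    )
    def test_invariants_hold_for_random_parameters(self, onset, peak_lag, amp, frac_t0, ret):
        k = DrugEffectKernel(
            onset_lead_min=onset,
            peak_lag_min=peak_lag,
            peak_amp_bpm=amp,
            value_at_t0_bpm=frac_t0 * amp,
            return_min=ret,
            threshold_bpm=5.0,
        )
        t = np.arange(-int(onset) - 10, 700, dtype=float)
        v = k(t)
        assert v[t < -onset].max(initial=0.0) == 0.0
        assert v[np.argmax(t >= peak_lag)] <= amp + 1e-9
        assert k(np.array([peak_lag]))[0] == pytest.approx(amp, rel=1e-12)
        assert k(np.array([ret]))[0] == pytest.approx(5.0, rel=1e-9)
        decay = v[t > peak_lag]
        assert (np.diff(decay) <= 1e-12).all()


class TestNightRetention:
    def test_uniform_wear_gives_quarter(self):
        assert night_retention_for_fraction(0.25, 1.0) == pytest.approx(1.0)

    def test_observed_share_value(self):
        # p = 1080 f / (360 (1 - f)) at the observed 18.7% night share
        assert night_retention_for_fraction(0.187, 1.0) == pytest.approx(
            3 * 0.187 / 0.813, rel=1e-12
        )
        assert night_retention_for_fraction(0.187, 1.0) == pytest.approx(0.690, abs=5e-4)

    def test_degenerate_or_infeasible(self):
        with pytest.raises(ParameterError):
            night_retention_for_fraction(0.0)
        with pytest.raises(ParameterError):
            night_retention_for_fraction(0.30, 1.0)  # above the 25% cap


class TestSimulation:
    def test_flat_config_constant_heart_rate(self):
        bundle = simulate_cohort(quiet_config())
        hr = bundle["p001"].hr.data
        assert (hr == 70.0).all()

    def test_constant_laba_offset_added(self):
        bundle = simulate_cohort(quiet_config(laba_offset_bpm=0.8, laba_fraction=1.0))
        assert (bundle["p001"].hr.data == 70.8).all()

    def test_fixed_seed_bit_identical(self):
        cfg = GeneratorConfig(n_patients=3, days_per_patient=5, rng_seed=42)
        assert simulate_cohort(cfg) == simulate_cohort(cfg)

    def test_empty_cohort(self):
        assert len(simulate_cohort(quiet_config(n_patients=0))) == 0

    def test_worn_minutes_bounded(self):
        cfg = GeneratorConfig(n_patients=4, days_per_patient=6, rng_seed=5)
        bundle = simulate_cohort(cfg)
        assert all(p.hr.n_minutes <= 6 * 1440 for p in bundle)

    def test_minute_means_converge_to_circadian_curve(self):
        # all effect amplitudes zero, noise on: per-minute-of-day mean over
        # many days approaches the cosinor curve within noise_sd / sqrt(n)
        circ = CircadianParams(mesor_bpm=70.0, amplitude_bpm=5.0, acrophase_min=900)
        cfg = quiet_config(
            n_patients=2, days_per_patient=60, circadian=circ, hr_noise_sd=6.0,
            rng_seed=9,
        )
        bundle = simulate_cohort(cfg)
        hr = pd.concat([p.hr.data for p in bundle])
        mod = hr.index.hour * 60 + hr.index.minute
        observed = hr.groupby(mod).mean()
        expected = circ.curve(observed.index.to_numpy())
        tol = 4 * 6.0 / np.sqrt(120)  # 4 sigma of the per-minute mean
        assert np.abs(observed.to_numpy() - expected).max() < tol

    def test_exercise_coupling_fraction(self):
        # with no background bouts, the share of reliever actuations with an
        # overlapping bout matches the configured coupling probability
        cfg = quiet_config(
            n_patients=5,
            days_per_patient=60,
            saba=SabaUseConfig(rate_per_day=0.8),
            exercise_coupling_prob=0.5,
            activity=ActivityConfig(bout_rate_per_day=0.0, hr_gain_bpm_per_step_rate=0.0),
            rng_seed=13,
        )
        bundle = simulate_cohort(cfg)
        coupled = total = 0
        for p in bundle:
            steps = p.steps.data
            for ts in pd.DatetimeIndex(p.events.of_type("SABA")["timestamp"]):
                total += 1
                window = steps.loc[ts - pd.Timedelta(minutes=30) : ts + pd.Timedelta(minutes=90)]
                coupled += int((window > 0).any())
        frac = coupled / total
        se = np.sqrt(0.25 / total)
        assert abs(frac - 0.5) < 4 * se

    def test_night_share_matches_solver_target(self):
        p = night_retention_for_fraction(0.187, day_retention=1.0)
        cfg = quiet_config(
            n_patients=10,
            days_per_patient=30,
            wear=WearConfig(night_retention=p, charge_gap_prob_per_day=0.0),
            rng_seed=21,
        )
        bundle = simulate_cohort(cfg)
        hr = pd.concat([pt.hr.data for pt in bundle])
        share = float(np.mean(hr.index.hour < 6))
        assert share == pytest.approx(0.187, abs=0.006)

    def test_morning_peak_profile_shape(self):
        prof = morning_peak_offset_profile(3.0, peak_hour=10)
        assert prof[10] == pytest.approx(3.0)
        assert prof.argmax() == 10

    def test_infeasible_reliever_rate_rejected(self):
        cfg = SabaUseConfig(rate_per_day=3.0)
        with pytest.raises(ParameterError):
            cfg.day_type_probs(0.0)
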