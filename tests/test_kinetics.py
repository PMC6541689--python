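"""Two-compartment kinetics and cohort generation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hepecv as h
from hepecv.kinetics import cohort_from_frame, cohort_to_frame


def rk4_interstitial(params, t_grid, dt=0.001):
    """Independent fixed-step RK4 integration of dCe/dt = k (Cp - Ce)."""
    k = params.exchange_rate

    def cp(t):
        return params.amp_fast * math.exp(-params.rate_fast * t) + (
            params.amp_slow * math.exp(-params.rate_slow * t)
        )

    def f(t, y):
        return k * (cp(t) - y)

    out = {}
    y, t = 0.0, 0.0
    targets = iter(sorted(t_grid))
    next_t = next(targets, None)
    while next_t is not None:
        if abs(t - next_t) < dt / 2:
            out[next_t] = y
            next_t = next(targets, None)
            continue
        k1 = f(t, y)
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return out


class TestPlasmaConcentration:
    def test_at_time_zero_equals_total_amplitude(self):
        p = h.KineticsParams(amp_fast=0.6, amp_slow=0.4)
        assert h.plasma_concentration(0.0, p) == pytest.approx(1.0)

    def test_pure_fast_decay_vanishes(self):
        p = h.KineticsParams(amp_fast=1.0, amp_slow=0.0, rate_fast=0.2, rate_slow=0.01)
        assert h.plasma_concentration(200.0, p) < 1e-10

    def test_matches_direct_arithmetic_at_15_minutes(self):
        p = h.KineticsParams(amp_fast=0.6, amp_slow=0.4, rate_fast=0.5, rate_slow=0.02)
        expected = 0.6 * math.exp(-0.5 * 15) + 0.4 * math.exp(-0.02 * 15)
        assert h.plasma_concentration(15.0, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            h.plasma_concentration(-1.0, h.KineticsParams())

    @settings(derandomize=True, max_examples=25)
    @given(
        rf=st.floats(0.1, 5.0),
        rs=st.floats(0.001, 0.09),
        af=st.floats(0.0, 2.0),
        as_=st.floats(0.01, 2.0),
    )
    def test_strictly_decreasing_for_positive_time(self, rf, rs, af, as_):
        p = h.KineticsParams(amp_fast=af, amp_slow=as_, rate_fast=rf, rate_slow=rs)
        t = np.linspace(0.0, 30.0, 200)
        c = h.plasma_concentration(t, p)
        assert np.all(np.diff(c) < 0)
        assert np.all(c > 0)


class TestInterstitialConcentration:
    def test_initial_condition_is_zero(self):
        assert h.interstitial_concentration(0.0, h.KineticsParams()) == 0.0

    def test_instant_equilibration_tracks_plasma(self):
        p = h.instant_equilibration_params(1e3)
        t = np.linspace(1.0, 30.0, 50)
        ce = h.interstitial_concentration(t, p)
        cp = h.plasma_concentration(t, p)
        assert np.all(np.abs(ce / cp - 1.0) < 1e-3)

    @pytest.mark.parametrize(
        "exchange_rate",
        [0.62, 1.5, 3.0, 0.02 + 1e-9, 10.0],
        ids=["default", "fast", "equal-to-rate-fast", "near-rate-slow", "very-fast"],
    )
    def test_closed_form_matches_rk4_oracle(self, exchange_rate):
        p = h.KineticsParams(exchange_rate=exchange_rate)
        t_grid = [1.0, 5.0, 15.0, 25.0, 30.0]
        oracle = rk4_interstitial(p, t_grid)
        for t, ref in oracle.items():
            got = h.interstitial_concentration(t, p)
            assert got == pytest.approx(ref, rel=1e-4)

    def test_exchange_equal_to_decay_rate_is_finite(self):
        p = h.KineticsParams(rate_fast=0.5, exchange_rate=0.5)
        val = h.interstitial_concentration(10.0, p)
        assert np.isfinite(val) and val > 0


class TestRelaxationRates:
    def test_native_rates_before_injection(self, control_subject):
        r1_liver, r1_blood = h.relaxation_rates(0.0, control_subject, h.KineticsParams())
        assert r1_liver == pytest.approx(1.0 / 593.3)
        assert r1_blood == pytest.approx(1.0 / 1600.0)

    def test_enhancement_linear_in_relaxivity(self, control_subject):
        p1 = h.KineticsParams(relaxivity_r1=5.0)
        p2 = h.KineticsParams(relaxivity_r1=10.0)
        for t in (5.0, 15.0):
            l1, b1 = h.relaxation_rates(t, control_subject, p1)
            l2, b2 = h.relaxation_rates(t, control_subject, p2)
            native_l, native_b = 1.0 / 593.3, 1.0 / 1600.0
            assert l2 - native_l == pytest.approx(2.0 * (l1 - native_l), rel=1e-12)
            assert b2 - native_b == pytest.approx(2.0 * (b1 - native_b), rel=1e-12)

    def test_hand_composed_values_at_15_minutes(self, control_subject):
        p = h.KineticsParams()
        cp = h.plasma_concentration(15.0, p)
        ce = h.interstitial_concentration(15.0, p)
        r1_liver, r1_blood = h.relaxation_rates(15.0, control_subject, p)
        assert r1_blood == pytest.approx(1.0 / 1600.0 + 0.005 * 0.55 * cp, rel=1e-12)
        assert r1_liver == pytest.approx(1.0 / 593.3 + 0.005 * 0.18 * ce, rel=1e-12)


class TestMeasuredECV:
    def test_equilibrium_limit_recovers_true_ve(self, control_subject):
        p = h.instant_equilibration_params(1e3)
        for t in (5.0, 15.0, 25.0):
            assert abs(h.true_measured_ecv(t, control_subject, p) - 0.18) < 1e-3

    def test_haematocrit_cancels(self, control_subject):
        p = h.KineticsParams()
        other = dataclasses.replace(control_subject, haematocrit=0.30)
        assert h.true_measured_ecv(15.0, control_subject, p) == pytest.approx(
            h.true_measured_ecv(15.0, other, p), rel=1e-12
        )

    def test_drift_bounded_and_non_decreasing(self, control_subject):
        subject = dataclasses.replace(control_subject, true_ve=0.30)
        p = h.default_kinetics_params()
        t = np.linspace(5.0, 25.0, 401)
        ecv = h.true_measured_ecv(t, subject, p)
        assert np.all(np.diff(ecv) >= -1e-12)
        assert 100.0 * (ecv[-1] - ecv[0]) <= 2.1

    def test_concentration_ratio_bounded(self, control_subject):
        p = h.default_kinetics_params()
        t = np.linspace(0.5, 40.0, 500)
        ratio = h.interstitial_concentration(t, p) / h.plasma_concentration(t, p)
        bound = p.exchange_rate / (p.exchange_rate - p.rate_slow)
        assert np.all(ratio >= 0.0)
        assert np.all(ratio <= bound + 1e-9)

    def test_pre_contrast_time_rejected(self, control_subject):
        with pytest.raises(ValueError):
            h.true_measured_ecv(0.0, control_subject, h.KineticsParams())


class TestGenerateCohort:
    def test_zero_subjects_gives_empty_list(self, default_specs):
        spec = dataclasses.replace(default_specs["control"], n_subjects=0)
        assert h.generate_cohort(spec) == []

    def test_zero_sds_give_exact_means(self, default_specs):
        spec = dataclasses.replace(
            default_specs["control"],
            ve_sd=0.0,
            native_t1_liver_sd=0.0,
            native_t1_blood_sd=0.0,
            haematocrit_sd=0.0,
            sirius_red_sd=0.0,
            portal_pressure_sd=0.0,
        )
        for s in h.generate_cohort(spec):
            assert s.true_ve == pytest.approx(spec.ve_mean)
            assert s.native_t1_liver == pytest.approx(spec.native_t1_liver_mean)
            assert s.haematocrit == pytest.approx(spec.haematocrit_mean)
            assert s.sirius_red == pytest.approx(spec.sirius_red_mean)
            assert s.portal_pressure == pytest.approx(spec.portal_pressure_mean)

    def test_seed_determinism_byte_identical(self, default_specs):
        spec = default_specs["ccl4_8wk"]
        a = cohort_to_frame(h.generate_cohort(spec)).to_csv(index=False)
        b = cohort_to_frame(h.generate_cohort(spec)).to_csv(index=False)
        assert a == b

    def test_sixteen_week_ve_mean_matches_calibration(self, default_specs):
        spec = default_specs["ccl4_16wk"]
        draws = []
        for seed in range(20):
            cohort = h.generate_cohort(dataclasses.replace(spec, seed=seed))
            draws.extend(s.true_ve for s in cohort)
        sem = spec.ve_sd / math.sqrt(len(draws))
        assert abs(np.mean(draws) - 0.305) < 2.0 * sem

    def test_group_ve_ordering(self, default_specs):
        means = {}
        for label, spec in default_specs.items():
            vals = []
            for seed in range(10):
                vals.extend(
                    s.true_ve for s in h.generate_cohort(dataclasses.replace(spec, seed=seed))
                )
            means[label] = np.mean(vals)
        assert means["control"] < means["ccl4_8wk"] < means["ccl4_16wk"]

    def test_hopeless_spec_raises_instead_of_looping(self, default_specs):
        spec = dataclasses.replace(
            default_specs["control"], haematocrit_mean=5.0, haematocrit_sd=0.001
        )
        with pytest.raises(RuntimeError):
            h.generate_cohort(spec)

    def test_frame_round_trip(self, default_specs):
        cohort = h.generate_cohort(default_specs["control"])
        again = cohort_from_frame(cohort_to_frame(cohort))
        assert again == cohort

    def test_physical_bounds_respected(self, default_specs):
        # control group: sirius mean 0.1 ± 0.1 presses against the 0 bound
        for seed in range(5):
            spec = dataclasses.replace(default_specs["control"], seed=seed)
            for s in h.generate_cohort(spec):
                assert 0.0 < s.true_ve < 1.0
                assert 0.0 < s.haematocrit < 1.0
                assert 0.0 <= s.sirius_red <= 100.0
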