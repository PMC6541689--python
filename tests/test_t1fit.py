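"""Polarity restoration, three-parameter IR fitting, Look-Locker correction."""

import math

import numpy as np
import pytest

import hepecv as h
from hepecv.molli import IRSignal, PhantomImageSeries, signed_recovery
from hepecv.t1fit import fit_t1_map, look_locker_correct


def make_signal(tis, mags, snr=np.inf):
    tis = np.asarray(tis, dtype=float)
    return IRSignal(
        inversion_times=tis,
        magnitudes=np.asarray(mags, dtype=float),
        group_index=np.zeros(len(tis), dtype=int),
        snr=snr,
    )


def series_from_signals(tis, magnitudes):
    """Wrap an (n_signals, n_ti) magnitude stack as a 1-row image series."""
    magnitudes = np.asarray(magnitudes, dtype=float)
    n_sig, n_ti = magnitudes.shape
    images = magnitudes.T.reshape(n_ti, n_sig, 1)
    return PhantomImageSeries(
        images=images,
        inversion_times=np.asarray(tis, dtype=float),
        group_index=np.zeros(n_ti, dtype=int),
        labels=np.ones((n_sig, 1), dtype=np.int16),
        truth_t1=np.zeros((n_sig, 1)),
        time_label="pre",
        scheme_text="",
        snr=np.nan,
    )


class TestScalarFit:
    @pytest.mark.parametrize("truth", [200.0, 400.0, 593.3, 800.0, 1200.0, 1600.0, 2000.0])
    def test_noiseless_round_trip_within_tenth_millisecond(self, truth):
        scheme = h.parse_scheme("4(10)10")
        sig = h.simulate_signal(truth, scheme, snr=np.inf)
        res = h.fit_signal(sig)
        assert res.converged
        assert abs(res.t1_corrected - truth) < 0.1

    def test_look_locker_identity_holds_on_every_result(self):
        scheme = h.parse_scheme("3(6)2(6)8")
        for truth in (300.0, 700.0, 1500.0):
            res = h.fit_signal(h.simulate_signal(truth, scheme, snr=50.0, seed=1))
            assert res.t1_corrected == pytest.approx(
                look_locker_correct(res.t1_star, res.a_amp, res.b_amp), rel=1e-12
            )

    def test_exact_model_parameters_recovered(self):
        # S = 1 - 1.75 exp(-TI/480): correction gives 480 * 0.75 = 360 ms
        tis = np.array([100.0, 300.0, 600.0, 1000.0, 1500.0, 2500.0, 4000.0])
        signed = 1.0 - 1.75 * np.exp(-tis / 480.0)
        res = h.fit_ir_three_param(tis, signed)
        assert res.a_amp == pytest.approx(1.0, rel=1e-4)
        assert res.b_amp == pytest.approx(1.75, rel=1e-4)
        assert res.t1_star == pytest.approx(480.0, rel=1e-4)
        assert res.t1_corrected == pytest.approx(360.0, rel=1e-4)

    def test_correction_fixed_point_when_b_is_twice_a(self):
        tis = np.array([50.0, 200.0, 500.0, 900.0, 1400.0, 2000.0, 3000.0])
        signed = 1.0 - 2.0 * np.exp(-tis / 600.0)
        res = h.fit_ir_three_param(tis, signed)
        assert res.t1_corrected == pytest.approx(res.t1_star, rel=1e-6)

    def test_constant_signal_flagged_not_raised(self):
        tis = np.array([100.0, 600.0, 1100.0, 1600.0, 2100.0])
        res = h.fit_ir_three_param(tis, np.full(5, 0.7))
        assert not res.converged

    def test_deterministic(self):
        sig = h.simulate_signal(650.0, h.parse_scheme("4(10)10"), snr=25.0, seed=9)
        r1, r2 = h.fit_signal(sig), h.fit_signal(sig)
        assert r1 == r2


class TestRestorePolarity:
    def test_flip_count_matches_analytic_null_point(self):
        truth, factor = 800.0, 0.8
        scheme = h.parse_scheme("4(10)10")
        sig = h.simulate_signal(truth, scheme, snr=np.inf)
        t1_star = factor * truth
        null_ti = t1_star * math.log(1.0 + truth / t1_star)
        expected_flips = int(np.sum(sig.inversion_times < null_ti))
        _, flip = h.restore_polarity(sig)
        assert flip == expected_flips

    def test_all_positive_short_t1_needs_no_flip(self):
        # null point ~81 ms lies below the earliest TI
        sig = h.simulate_signal(100.0, h.parse_scheme("5"), snr=np.inf)
        signed, flip = h.restore_polarity(sig)
        assert flip == 0
        np.testing.assert_array_equal(signed, sig.magnitudes)

    def test_restored_signs_recover_signed_curve(self):
        truth = 600.0
        sig = h.simulate_signal(truth, h.parse_scheme("3(6)2(6)8"), snr=np.inf)
        signed, _ = h.restore_polarity(sig)
        np.testing.assert_allclose(
            signed, signed_recovery(sig.inversion_times, truth), atol=1e-10
        )


class TestMapFit:
    def test_noiseless_phantom_map_equals_truth(self, control_subject):
        series = h.simulate_phantom(control_subject, h.KineticsParams(), "pre", snr=np.inf)
        t1_map = fit_t1_map(series)
        tissue = series.labels > 0
        assert t1_map.validity_mask[tissue].all()
        spread = np.ptp(t1_map.t1_values[series.labels == 1])
        assert spread < 0.1
        np.testing.assert_allclose(
            t1_map.t1_values[tissue], series.truth_t1[tissue], atol=0.1
        )

    def test_background_voxels_masked_invalid(self, control_subject):
        series = h.simulate_phantom(control_subject, h.KineticsParams(), "pre", snr=40.0, seed=1)
        t1_map = fit_t1_map(series)
        background = series.labels == 0
        assert not t1_map.validity_mask[background].any()
        assert np.isnan(t1_map.t1_values[background]).all()

    def test_map_agrees_with_scalar_path_on_noisy_voxels(self):
        rng = np.random.default_rng(4)
        scheme = h.parse_scheme("3(6)2(6)8")
        tis, gidx = h.inversion_times(scheme)
        signals = [h.simulate_signal(600.0, scheme, snr=40.0, seed=rng) for _ in range(15)]
        series = series_from_signals(tis, [s.magnitudes for s in signals])
        t1_map = fit_t1_map(series)
        for i, sig in enumerate(signals):
            scalar = h.fit_signal(sig)
            assert t1_map.t1_values[i, 0] == pytest.approx(scalar.t1_corrected, rel=5e-4)

    def test_mean_bias_below_one_percent_at_snr_40(self):
        scheme = h.parse_scheme("4(10)10")
        tis, _ = h.inversion_times(scheme)
        rng = np.random.default_rng(12)
        truth = 600.0
        signed = signed_recovery(tis, truth)
        mags = np.abs(signed[None, :] + rng.normal(0.0, 1.0 / 40.0, (1000, len(tis))))
        t1_map = fit_t1_map(series_from_signals(tis, mags))
        est = t1_map.t1_values[t1_map.validity_mask]
        assert len(est) > 950
        assert abs(est.mean() - truth) < 0.01 * truth

    def test_fit_beats_exhaustive_grid_search_oracle(self):
        # the fitted residual can never exceed a brute-force 3-D grid search
        scheme = h.parse_scheme("4(10)10")
        tis, _ = h.inversion_times(scheme)
        rng = np.random.default_rng(7)
        truth = 700.0
        signed_true = signed_recovery(tis, truth)
        a_grid = np.linspace(0.8, 1.2, 21)
        b_grid = np.linspace(1.8, 2.7, 21)
        t1s_grid = np.linspace(300.0, 900.0, 121)
        for _ in range(10):
            mags = np.abs(signed_true + rng.normal(0.0, 1.0 / 40.0, len(tis)))
            sig = make_signal(tis, mags, snr=40.0)
            signed, _ = h.restore_polarity(sig)
            res = h.fit_ir_three_param(tis, signed)
            model = (
                a_grid[:, None, None, None]
                - b_grid[None, :, None, None]
                * np.exp(-tis[None, None, None, :] / t1s_grid[None, None, :, None])
            )
            sse = ((model - signed) ** 2).sum(axis=-1)
            oracle_best = sse.min()
            fit_sse = res.residual_rms**2 * len(tis)
            assert fit_sse <= oracle_best + 1e-12
            # and the oracle's argmin T1 (corrected) lies near the fit
            idx = np.unravel_index(np.argmin(sse), sse.shape)
            t1_oracle = look_locker_correct(
                t1s_grid[idx[2]], a_grid[idx[0]], b_grid[idx[1]]
            )
            assert abs(t1_oracle - res.t1_corrected) < 60.0

    def test_map_noise_matches_single_voxel_monte_carlo(self, control_subject):
        series = h.simulate_phantom(
            control_subject, h.KineticsParams(), "pre", snr=40.0, seed=21
        )
        t1_map = fit_t1_map(series)
        liver = (series.labels == 1) & t1_map.validity_mask
        map_sd = t1_map.t1_values[liver].std(ddof=1)

        scheme = h.parse_scheme("4(10)10")
        tis, _ = h.inversion_times(scheme)
        truth = series.truth_t1[series.labels == 1][0]
        rng = np.random.default_rng(22)
        signed = signed_recovery(tis, truth)
        mags = np.abs(signed[None, :] + rng.normal(0.0, 1.0 / 40.0, (400, len(tis))))
        mc_map = fit_t1_map(series_from_signals(tis, mags))
        mc_sd = mc_map.t1_values[mc_map.validity_mask].std(ddof=1)
        assert map_sd / mc_sd < 1.3
        assert mc_sd / map_sd < 1.3

    def test_dimension_mismatch_rejected(self, control_subject):
        series = h.simulate_phantom(control_subject, h.KineticsParams(), "pre", snr=np.inf)
        with pytest.raises(ValueError):
            PhantomImageSeries(
                images=series.images[:-1],
                inversion_times=series.inversion_times,
                group_index=series.group_index,
                labels=series.labels,
                truth_t1=series.truth_t1,
                time_label="pre",
                scheme_text=series.scheme_text,
                snr=np.inf,
            )

    def test_map_fit_deterministic(self, control_subject):
        series = h.simulate_phantom(control_subject, h.KineticsParams(), "post5", snr=30.0, seed=2)
        m1, m2 = fit_t1_map(series), fit_t1_map(series)
        np.testing.assert_array_equal(m1.t1_values, m2.t1_values)
        np.testing.assert_array_equal(m1.validity_mask, m2.validity_mask)
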