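"""Quantification chain: baseline, drift, correction, calibration, activity."""

import warnings

import numpy as np
import pytest

from efqokit import standard_config
from efqokit.errors import CalibrationError, TraceValidationError
from efqokit.quantify import (
    NonPlateauWarning,
    aggregate_replicates,
    compute_activity,
    correct_trace,
    estimate_baseline,
    estimate_drift,
    estimate_plateau,
    fit_calibration,
    initial_rate,
    quantify_plate,
)
from efqokit.simulate import integrated_mm_substrate, simulate_plate, simulate_trace
from efqokit.types import ActivityResult, CalibrationModel, CorrectedTrace, KineticTrace

from conftest import true_initial_rate_au


def _trace(y, role="sample", dt=5.0):
    t = np.arange(len(y)) * dt
    return KineticTrace("B01", t, np.asarray(y, dtype=float), role)


def _corr(times, values):
    return CorrectedTrace("B01", np.asarray(times, float), np.asarray(values, float),
                          0.0, 0.0, 0.0)


class TestBaseline:
    def test_first_read_default(self):
        assert estimate_baseline(_trace([100, 105, 110])) == 100

    def test_mean_of_first_m(self):
        assert estimate_baseline(_trace([100, 102, 300]), m=2) == 101

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            estimate_baseline(_trace([1, 2]), m=3)


class TestDrift:
    def test_constant_control_has_zero_drift(self):
        slope, _ = estimate_drift(_trace([100.0] * 10, role="substrate_control"))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        t = np.arange(10) * 5.0
        tr = KineticTrace("A01", t, 100 + 2 * t, "enzyme_control")
        slope, stderr = estimate_drift(tr)
        assert slope == pytest.approx(2.0)
        assert stderr == pytest.approx(0.0, abs=1e-12)

    def test_seeded_noisy_control_ci_covers_truth(self):
        cfg = standard_config(drift_substrate=0.5, noise_sd=2.0)
        tr = simulate_trace(cfg, "substrate_control", seed=123)
        assert tr.n_reads == 145
        slope, stderr = estimate_drift(tr)
        assert abs(slope - 0.5) <= 1.96 * stderr

    def test_sample_role_rejected(self):
        with pytest.raises(TraceValidationError):
            estimate_drift(_trace([1, 2, 3], role="sample"))


class TestCorrection:
    def test_constant_trace_corrects_to_zero(self):
        tr = _trace([100.0] * 8)
        out = correct_trace(tr, 100.0, 0.0, 0.0)
        assert np.allclose(out.corrected, 0.0)

    def test_linear_algebraic_case(self):
        t = np.arange(11) * 1.0
        tr = KineticTrace("B01", t, 100 + 5 * t, "sample")
        out = correct_trace(tr, 100.0, 1.0, 2.0)
        assert np.allclose(out.corrected, 2 * t)
        assert out.corrected[10] == pytest.approx(20.0)

    def test_exact_inverse_of_simulator(self, clean_config):
        cfg = clean_config
        s = simulate_trace(cfg, "sample")
        out = correct_trace(s, estimate_baseline(s),
                            cfg.drift_substrate, cfg.drift_enzyme)
        truth = cfg.k_AU * cfg.volume * (
            cfg.S0 - integrated_mm_substrate(cfg.S0, cfg.Km, cfg.Vmax, s.times))
        assert np.max(np.abs(out.corrected - truth)) < 1e-9  # machine precision (AU ~1e3)

    def test_affine_linearity(self):
        t = np.arange(10) * 5.0
        y = 100 + 3 * t + np.sin(t)
        tr1 = KineticTrace("B01", t, y, "sample")
        tr2 = KineticTrace("B01", t, 2 * y, "sample")
        out1 = correct_trace(tr1, 100.0, 0.5, 0.5)
        out2 = correct_trace(tr2, 200.0, 1.0, 1.0)
        assert np.allclose(out2.corrected, 2 * out1.corrected)

    def test_control_role_rejected(self):
        with pytest.raises(TraceValidationError):
            correct_trace(_trace([1, 2, 3], role="enzyme_control"), 1.0, 0.0, 0.0)


class TestPlateau:
    def test_constant_tail(self):
        y = np.concatenate([np.linspace(0, 1000, 20), np.full(20, 1000.0)])
        assert estimate_plateau(_trace(y)) == pytest.approx(1000.0)

    def test_fully_digested_noise_free_plateau(self):
        cfg = standard_config(noise_sd=0.0, quench_efficiency=1.0, Vmax=1e-7,
                              drift_substrate=0.0, drift_enzyme=0.0)
        s = simulate_trace(cfg, "sample")
        corr = correct_trace(s, estimate_baseline(s), 0.0, 0.0)
        assert estimate_plateau(corr) == pytest.approx(1000.0, rel=1e-6)

    def test_still_rising_trace_warns(self):
        t = np.arange(30) * 5.0
        with pytest.warns(NonPlateauWarning):
            estimate_plateau(_corr(t, 3.0 * t))

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            estimate_plateau(_trace([1, 2, 3]), m=10)


class TestCalibration:
    def test_exact_line_through_origin(self):
        model = fit_calibration([1e-10, 2e-10], [1000.0, 2000.0])
        assert model.k == pytest.approx(1e13)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)
        assert model.r_squared == pytest.approx(1.0)

    def test_simulated_dilution_series_recovers_k(self):
        amounts, imaxs = [], []
        for S0 in (0.25e-6, 0.5e-6, 1e-6, 2e-6):
            cfg = standard_config(noise_sd=0.0, quench_efficiency=1.0,
                                  Vmax=5e-8, S0=S0)
            s = simulate_trace(cfg, "sample")
            corr = correct_trace(s, estimate_baseline(s),
                                 cfg.drift_substrate, cfg.drift_enzyme)
            amounts.append(S0 * cfg.volume)
            imaxs.append(estimate_plateau(corr))
        model = fit_calibration(amounts, imaxs)
        assert model.k == pytest.approx(1e13, rel=1e-3)

    def test_single_amount_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([1e-10, 1e-10], [1000.0, 1001.0])

    def test_negative_slope_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([1e-10, 2e-10], [2000.0, 1000.0])


class TestInitialRate:
    def test_linear_trace_any_policy(self):
        t = np.arange(30) * 5.0
        for policy in ("initial_window", "max_rolling"):
            slope, window, r2 = initial_rate(_corr(t, 3.0 * t), policy=policy)
            assert slope == pytest.approx(3.0)
            assert r2 == pytest.approx(1.0)

    def test_flat_trace_zero_slope(self):
        t = np.arange(20) * 5.0
        slope, _, _ = initial_rate(_corr(t, np.zeros_like(t)))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_mm_simulation_matches_analytic_rate(self):
        # S0 = 10·Km keeps the enzyme saturated: the early chord tracks the
        # analytic initial rate closely even while substrate is consumed
        cfg = standard_config(noise_sd=0.0, quench_efficiency=1.0,
                              S0=1e-5, Km=1e-6, Vmax=1e-8)
        s = simulate_trace(cfg, "sample")
        corr = correct_trace(s, estimate_baseline(s),
                             cfg.drift_substrate, cfg.drift_enzyme)
        slope, _, _ = initial_rate(corr)
        assert slope == pytest.approx(true_initial_rate_au(cfg), rel=0.02)

    def test_short_trace_shrinks_window_with_warning(self):
        t = np.arange(6) * 5.0
        with pytest.warns(UserWarning, match="window"):
            slope, _, _ = initial_rate(_corr(t, 2.0 * t), window=12)
        assert slope == pytest.approx(2.0)

    def test_too_few_reads_rejected(self):
        t = np.arange(3) * 5.0
        with pytest.raises(TraceValidationError):
            initial_rate(_corr(t, t))


class TestActivity:
    def _calib(self, k=4.0):
        return CalibrationModel(k=k, intercept=0.0, r_squared=1.0,
                                substrate_amounts=np.array([]),
                                imax_values=np.array([]), n_points=0)

    def test_activity_is_slope_over_k(self):
        t = np.arange(20) * 5.0
        res = compute_activity(_corr(t, 2.0 * t), self._calib(k=4.0))
        assert res.activity == pytest.approx(0.5)
        assert res.rate_slope == pytest.approx(2.0)

    def test_specific_activity_division(self):
        t = np.arange(20) * 5.0
        res = compute_activity(_corr(t, 4e-12 * t), self._calib(k=4.0),
                               protein_mass=5e-4)
        assert res.activity == pytest.approx(1e-12)
        assert res.specific_activity == pytest.approx(2e-9)

    def test_noise_free_well_recovers_generative_activity(self, clean_config):
        cfg = clean_config
        s = simulate_trace(cfg, "sample")
        corr = correct_trace(s, estimate_baseline(s),
                             cfg.drift_substrate, cfg.drift_enzyme)
        res = compute_activity(corr, self._calib(k=cfg.k_AU))
        truth = cfg.volume * cfg.Vmax * cfg.S0 / (cfg.Km + cfg.S0)
        assert res.activity == pytest.approx(truth, rel=0.02)

    def test_negative_slope_flagged_not_truncated(self):
        t = np.arange(20) * 5.0
        res = compute_activity(_corr(t, -1.0 * t), self._calib())
        assert res.below_detection
        assert res.activity < 0

    def test_invalid_calibration_rejected(self):
        t = np.arange(20) * 5.0
        bad = CalibrationModel(k=0.0, intercept=0.0, r_squared=1.0,
                               substrate_amounts=np.array([]),
                               imax_values=np.array([]), n_points=0)
        with pytest.raises(CalibrationError):
            compute_activity(_corr(t, t), bad)

    def test_scale_equivariance_in_k(self, clean_config):
        """Doubling the generative fluorescence coefficient and refitting the
        calibration leaves the molar activity unchanged (AU units cancel)."""
        activities = []
        for k_au in (1e13, 2e13):
            cfg = clean_config.with_(k_AU=k_au)
            amounts, imaxs = [], []
            for S0 in (0.5e-6, 1e-6, 2e-6):
                c2 = cfg.with_(S0=S0, Vmax=5e-8)
                s2 = simulate_trace(c2, "sample")
                corr2 = correct_trace(s2, estimate_baseline(s2),
                                      c2.drift_substrate, c2.drift_enzyme)
                amounts.append(S0 * c2.volume)
                imaxs.append(estimate_plateau(corr2))
            calib = fit_calibration(amounts, imaxs)
            s = simulate_trace(cfg, "sample")
            corr = correct_trace(s, estimate_baseline(s),
                                 cfg.drift_substrate, cfg.drift_enzyme)
            activities.append(compute_activity(corr, calib).activity)
        assert activities[0] == pytest.approx(activities[1], rel=1e-6)


class TestAggregate:
    def _res(self, well, activity, cond="c"):
        return ActivityResult(well, cond, activity, None, 0.0, activity,
                              (0.0, 55.0), 1.0)

    def test_mean_and_sem(self):
        agg = aggregate_replicates([self._res("B01", 2.0), self._res("B02", 4.0)])
        assert agg[0].mean == pytest.approx(3.0)
        assert agg[0].sem == pytest.approx(1.0)
        assert agg[0].n == 2

    def test_single_replicate_has_no_sem(self):
        agg = aggregate_replicates([self._res("B01", 5.0)])
        assert agg[0].mean == 5.0 and agg[0].sem is None

    def test_identical_replicates_zero_sem(self):
        agg = aggregate_replicates([self._res(w, 7.0) for w in ("B01", "B02", "B03")])
        assert agg[0].sem == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])


class TestQuantifyPlate:
    def test_missing_controls_rejected(self, clean_config):
        ds = simulate_plate([("B01", "sample", {})], clean_config, seed=0)
        calib = CalibrationModel(k=1e13, intercept=0.0, r_squared=1.0,
                                 substrate_amounts=np.array([]),
                                 imax_values=np.array([]), n_points=0)
        with pytest.raises(TraceValidationError):
            quantify_plate(ds, calib)

    def test_full_chain_recovers_generative_activity(self, standard_plate,
                                                     clean_config):
        calib = CalibrationModel(k=clean_config.k_AU, intercept=0.0,
                                 r_squared=1.0, substrate_amounts=np.array([]),
                                 imax_values=np.array([]), n_points=0)
        results = quantify_plate(standard_plate, calib)
        truth = clean_config.volume * clean_config.Vmax * clean_config.S0 / (
            clean_config.Km + clean_config.S0)
        assert len(results) == 3
        for r in results:
            assert r.activity == pytest.approx(truth, rel=0.02)
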