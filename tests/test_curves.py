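"""Curve engine: baseline subtraction, sigmoid fitting, Cq methods, detection."""

import numpy as np
import pytest

import allelecall as ac
from allelecall.curves import (
    compute_cq,
    detect_amplification,
    endpoint_rfu,
    fit_sigmoid,
    model_predict,
    subtract_background,
)
from allelecall.model import Reaction, SettingsError
from conftest import clean_b4


class TestBackground:
    def test_flat_trace_goes_to_zero(self):
        cycles = np.arange(1, 41)
        corrected = subtract_background(np.full(40, 100.0), cycles, (5, 15))
        assert np.allclose(corrected, 0.0, atol=1e-9)

    def test_exact_linear_baseline_removed_everywhere(self):
        cycles = np.arange(1, 41, dtype=float)
        corrected = subtract_background(2.0 * cycles + 50.0, cycles, (5, 15))
        assert np.allclose(corrected, 0.0, atol=1e-9)

    def test_drifting_sigmoid_recovered(self):
        x, y = clean_b4(e=22.0)
        corrected = subtract_background(y + 0.5 * x + 50.0, x, (5, 15))
        # within a small bias of the drift-free sigmoid (the sigmoid foot
        # leaks slightly into the background window)
        assert np.max(np.abs(corrected - y)) < 25.0

    def test_bg_range_outside_trace_is_settings_error(self):
        with pytest.raises(SettingsError):
            subtract_background(np.zeros(40), np.arange(1, 41), (50, 60))


class TestFit:
    def test_noise_free_b4_parameters_recovered(self):
        x, y = clean_b4(e=20.0, k=0.8, d=1000.0)
        fit = fit_sigmoid(y, x, "b4")
        assert fit.converged
        assert fit.b == pytest.approx(-0.8, rel=1e-4)
        assert fit.c == pytest.approx(0.0, abs=1e-3)
        assert fit.d == pytest.approx(1000.0, rel=1e-4)
        assert fit.e == pytest.approx(20.0, rel=1e-4)

    @pytest.mark.parametrize("model", ["l4", "l5", "b5"])
    def test_other_models_fit_their_own_curves(self, model):
        x = np.arange(1, 41, dtype=float)
        y = model_predict(model, x, -0.9 if model.startswith("b") else -12.0,
                          0.0, 800.0, 20.0, 1.3 if model.endswith("5") else 1.0)
        fit = fit_sigmoid(y, x, model)
        assert fit.converged
        assert np.max(np.abs(
            model_predict(model, x, fit.b, fit.c, fit.d, fit.e, fit.f) - y
        )) < 1.0

    def test_constant_trace_degenerates(self):
        x = np.arange(1, 41, dtype=float)
        fit = fit_sigmoid(np.full(40, 3.0), x, "b4")
        assert (not fit.converged) or fit.amplitude < 1.0

    def test_monte_carlo_inflection_recovery(self):
        """Noisy (sigma = 0.5% amplitude) fits recover e within 0.1 cycles."""
        x, y = clean_b4(e=20.0, d=1000.0)
        rng = np.random.default_rng(123)
        hits = 0
        n = 100
        for _ in range(n):
            fit = fit_sigmoid(y + rng.normal(0, 5.0, len(x)), x, "b4")
            if fit.converged and abs(fit.e - 20.0) <= 0.1:
                hits += 1
        assert hits >= 95


class TestCq:
    def test_cpd1_is_inflection_of_b4(self):
        x, y = clean_b4(e=20.0, k=0.8)
        fit = fit_sigmoid(y, x, "b4")
        assert compute_cq(fit, "cpD1", (1, 40)) == pytest.approx(20.0, abs=0.01)

    def test_cpd2_matches_closed_form(self):
        """Second-derivative max of a logistic sits at e - ln(2+sqrt(3))/k."""
        for k in (0.5, 0.8, 1.2):
            x, y = clean_b4(e=20.0, k=k)
            fit = fit_sigmoid(y, x, "b4")
            expected = 20.0 - np.log(2.0 + np.sqrt(3.0)) / k
            assert compute_cq(fit, "cpD2", (1, 40)) == pytest.approx(expected, abs=0.01)

    def test_grid_refined_argmax_agrees_with_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            e = rng.uniform(15, 25)
            k = rng.uniform(0.4, 1.2)
            x, y = clean_b4(e=e, k=k)
            fit = fit_sigmoid(y, x, "b4")
            grid = np.arange(1, 40, 0.001)
            d1 = np.gradient(model_predict("b4", grid, fit.b, fit.c, fit.d,
                                           fit.e, fit.f), grid)
            brute = grid[np.argmax(d1)]
            assert compute_cq(fit, "cpD1", (1, 40)) == pytest.approx(brute, abs=0.002)

    def test_cpd2_precedes_cpd1(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x, y = clean_b4(e=rng.uniform(16, 24), k=rng.uniform(0.4, 1.2))
            fit = fit_sigmoid(y, x, "b4")
            assert compute_cq(fit, "cpD2", (1, 40)) < compute_cq(fit, "cpD1", (1, 40))

    def test_orientation_invariance(self):
        """A mirrored (decreasing) parameterization yields the same Cq."""
        x, y = clean_b4(e=20.0, k=0.8)
        fit = fit_sigmoid(y, x, "b4")
        mirrored = ac.SigmoidFit(model_type="b4", b=-fit.b, c=fit.d, d=fit.c,
                                 e=fit.e, f=1.0, rss=fit.rss, converged=True)
        for method in ("cpD1", "cpD2", "expR", "Cy20"):
            assert compute_cq(mirrored, method, (1, 40)) == pytest.approx(
                compute_cq(fit, method, (1, 40)), abs=0.01
            )

    def test_every_method_orders_sensibly(self):
        x, y = clean_b4(e=20.0, k=0.8)
        fit = fit_sigmoid(y, x, "b4")
        exp_r = compute_cq(fit, "expR", (1, 40))
        cy20 = compute_cq(fit, "Cy20", (1, 40))
        cpd2 = compute_cq(fit, "cpD2", (1, 40))
        cpd1 = compute_cq(fit, "cpD1", (1, 40))
        assert exp_r < cpd2 < cpd1
        assert cy20 < cpd1

    def test_non_converged_fit_has_no_cq(self):
        assert compute_cq(ac.SigmoidFit(model_type="b4"), "cpD1", (1, 40)) is None


class TestEquivariance:
    def test_scale_equivariance(self, settings):
        x, y = clean_b4(e=20.0)
        for s in (0.5, 3.0):
            fit1 = fit_sigmoid(y, x, "b4")
            fit2 = fit_sigmoid(s * y, x, "b4")
            assert fit2.amplitude == pytest.approx(s * fit1.amplitude, rel=1e-3)
            assert endpoint_rfu(s * y) == pytest.approx(s * endpoint_rfu(y), rel=1e-9)
            for m in ("cpD1", "cpD2"):
                assert compute_cq(fit2, m, (1, 40)) == pytest.approx(
                    compute_cq(fit1, m, (1, 40)), abs=0.01
                )

    def test_cycle_shift_equivariance(self):
        x, _ = clean_b4()
        for delta in (-2.0, 1.5):
            y1 = model_predict("b4", x, -0.8, 0.0, 1000.0, 20.0)
            y2 = model_predict("b4", x, -0.8, 0.0, 1000.0, 20.0 + delta)
            f1, f2 = fit_sigmoid(y1, x, "b4"), fit_sigmoid(y2, x, "b4")
            for m in ("cpD1", "cpD2", "expR", "Cy20"):
                assert compute_cq(f2, m, (1, 40)) - compute_cq(f1, m, (1, 40)) \
                    == pytest.approx(delta, abs=0.02)


class TestDetection:
    def _analyze(self, rfu, settings):
        r = Reaction("T_A", "FAM", np.arange(1, len(rfu) + 1), rfu)
        return ac.analyze_reaction(r, settings)

    def test_flat_noisy_trace_is_no_amp(self, settings):
        rng = np.random.default_rng(0)
        res = self._analyze(rng.normal(100, 5, 40), settings)
        assert res.amp_status == "no_amp"
        assert res.cq is None

    def test_clean_sigmoid_is_ok(self, settings):
        _, y = clean_b4(e=18.0)
        res = self._analyze(y + 50.0, settings)
        assert res.amp_status == "ok"
        assert res.cq == pytest.approx(18.0, abs=0.05)

    def test_late_rise_is_no_amp(self, settings):
        """A rise starting near the last cycles must not count as amplified."""
        x = np.arange(1, 41, dtype=float)
        y = model_predict("b4", x, -0.8, 0.0, 1000.0, 42.0) + 50.0
        res = self._analyze(y, settings)
        assert res.amp_status == "no_amp"

    def test_endpoint_is_mean_of_last_three(self):
        assert endpoint_rfu(np.array([0.0, 990.0, 1000.0, 1010.0])) == 1000.0
        assert endpoint_rfu(np.zeros(10)) == 0.0

    def test_file_cq_used_when_preprocessing_off(self, settings):
        from dataclasses import replace
        raw_settings = replace(settings, preprocess=False)
        _, y = clean_b4(e=19.0)
        r = Reaction("T_A", "FAM", np.arange(1, 41), y, preprocessed_cq=19.0)
        res = ac.analyze_reaction(r, raw_settings)
        assert res.amp_status == "ok"
        assert res.cq == 19.0
        # without a file Cq the reaction cannot be scored as amplified
        r2 = Reaction("T_A", "FAM", np.arange(1, 41), y, preprocessed_cq=None)
        assert ac.analyze_reaction(r2, raw_settings).amp_status == "no_amp"
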