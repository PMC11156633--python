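import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from calaudit.calibration_metrics import (CalibrationError,
                                          DegenerateOutcomeError,
                                          FrozenLoessDesign, SmoothedCurve,
                                          UnidentifiableSlopeError, brier,
                                          clipped_logit, eavg_emax,
                                          fit_loess_curve,
                                          fit_weak_calibration,
                                          moderate_calibration,
                                          _weak_from_logits)
from conftest import make_scored_outcomes


@pytest.mark.parametrize("p, eps, expected", [
    (0.5, 1e-6, 0.0),
    (0.73, 1e-6, np.log(0.73 / 0.27)),
    (0.0, 1e-6, np.log(1e-6 / (1 - 1e-6))),
    (1.0, 1e-6, -np.log(1e-6 / (1 - 1e-6))),
])
def test_clipped_logit_values(p, eps, expected):
    assert clipped_logit(p, eps) == pytest.approx(expected, abs=1e-10)


@given(st.floats(1e-5, 1 - 1e-5))
@settings(max_examples=50, deadline=None)
def test_clipped_logit_inverts_expit_inside_clip_range(p):
    assert expit(clipped_logit(p)) == pytest.approx(p, abs=1e-12)


class TestWeakCalibration:
    def test_matches_statsmodels_mle(self, miscalibrated_sample):
        """Joint fit and offset fit agree with an independent GLM fitter."""
        p, y = miscalibrated_sample
        w = fit_weak_calibration(p, y)
        x = clipped_logit(p)
        joint = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert w.intercept == pytest.approx(joint.params[0], abs=1e-6)
        assert w.slope == pytest.approx(joint.params[1], abs=1e-6)
        offset = sm.GLM(y, np.ones((len(y), 1)), offset=x,
                        family=sm.families.Binomial()).fit()
        assert w.citl == pytest.approx(offset.params[0], abs=1e-6)

    def test_recovers_identity_calibration(self):
        p, y = make_scored_outcomes(0.0, 1.0, 100_000, seed=3)
        w = fit_weak_calibration(p, y)
        assert abs(w.intercept) < 0.05
        assert abs(w.slope - 1.0) < 0.05

    def test_recovers_gender_scale_miscalibration(self):
        """Truth of the magnitude seen for female patients in the audit."""
        p, y = make_scored_outcomes(-1.49, 1.42, 100_000, seed=4)
        w = fit_weak_calibration(p, y)
        assert w.intercept == pytest.approx(-1.49, abs=0.05)
        assert w.slope == pytest.approx(1.42, abs=0.05)

    def test_logit_shift_moves_citl_not_slope(self, miscalibrated_sample):
        p, y = miscalibrated_sample
        delta = 0.7
        w0 = fit_weak_calibration(p, y)
        w1 = fit_weak_calibration(expit(clipped_logit(p) + delta), y)
        assert w1.slope == pytest.approx(w0.slope, abs=1e-8)
        assert w1.citl == pytest.approx(w0.citl - delta, abs=1e-6)

    def test_degenerate_inputs_raise(self):
        p = np.linspace(0.1, 0.9, 50)
        with pytest.raises(DegenerateOutcomeError):
            fit_weak_calibration(p, np.zeros(50))
        y = np.tile([0, 1], 25)
        with pytest.raises(UnidentifiableSlopeError):
            fit_weak_calibration(np.full(50, 0.4), y)
        with pytest.raises(CalibrationError):
            fit_weak_calibration(p[:10], y[:10])

    def test_weighted_fit_equals_expanded_fit(self, miscalibrated_sample):
        """Count-weighted refit (bootstrap fast path) = fit on expanded data."""
        p, y = miscalibrated_sample
        p, y = p[:800], y[:800]
        rng = np.random.default_rng(0)
        counts = np.bincount(rng.integers(0, 800, 800), minlength=800).astype(float)
        x = clipped_logit(p)
        aw, bw, cw = _weak_from_logits(x, y, counts)
        rep = np.repeat(np.arange(800), counts.astype(int))
        w = fit_weak_calibration(p[rep], y[rep])
        assert aw == pytest.approx(w.intercept, abs=1e-6)
        assert bw == pytest.approx(w.slope, abs=1e-6)
        assert cw == pytest.approx(w.citl, abs=1e-6)


class TestBrier:
    def test_perfect_predictions_score_zero(self):
        y = np.array([0.0, 1.0, 1.0, 0.0] * 10)
        assert brier(y, y).brier == 0.0

    def test_constant_prevalence_predictor_identity(self):
        y = np.array([1] * 7 + [0] * 13, dtype=float)
        ybar = y.mean()
        scores = brier(np.full_like(y, ybar), y)
        assert scores.brier == pytest.approx(ybar * (1 - ybar), abs=1e-15)
        assert scores.brier_scaled == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        scores = brier(np.array([0.8, 0.2, 0.6]), np.array([1, 0, 0]))
        assert scores.brier == pytest.approx((0.04 + 0.04 + 0.36) / 3, abs=1e-12)

    def test_single_class_flags_scaled_undefined(self):
        scores = brier(np.array([0.2, 0.3]), np.array([0, 0]))
        assert scores.brier_scaled is None
        assert np.isfinite(scores.brier)


def brute_force_loess(x, y, grid, span, degree):
    """Independent loess oracle: explicit tricube WLS per evaluation point."""
    n = len(x)
    r = min(n, max(int(np.ceil(span * n)), degree + 2))
    out = []
    for x0 in grid:
        d = np.abs(x - x0)
        h = np.sort(d)[r - 1]
        w = (1 - np.clip(d / h, 0, 1) ** 3) ** 3
        sw = np.sqrt(w)
        basis = np.vander(x - x0, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(basis * sw[:, None], y * sw, rcond=None)
        out.append(coef[0])
    return np.array(out)


class TestLoess:
    def test_constant_response_reproduced(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, 100)
        curve = fit_loess_curve(p, np.full(100, 0.3))
        assert np.allclose(curve.fitted, 0.3, atol=1e-10)

    @pytest.mark.parametrize("span", [0.3, 0.75, 1.0])
    def test_local_linear_reproduces_global_line(self, span):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.8, 150)
        y = 0.1 + 0.8 * p
        curve = fit_loess_curve(p, y, span=span, degree=1)
        expected = 0.1 + 0.8 * curve.eval_points
        assert np.allclose(curve.fitted, expected, atol=1e-8)

    @pytest.mark.parametrize("degree", [0, 1, 2])
    @pytest.mark.parametrize("span", [0.4, 0.75])
    def test_matches_brute_force_oracle(self, degree, span):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.02, 0.98, 200)
        y = (rng.random(200) < p).astype(float)
        curve = fit_loess_curve(p, y, span=span, degree=degree)
        oracle = np.clip(
            brute_force_loess(p, y, curve.eval_points, span, degree), 0, 1)
        assert np.allclose(curve.fitted, oracle, atol=1e-8)

    def test_too_few_distinct_predictions_raise(self):
        p = np.tile([0.2, 0.4], 15)
        y = np.tile([0.0, 1.0], 15)
        with pytest.raises(CalibrationError):
            fit_loess_curve(p, y, degree=2)

    def test_eval_grid_capped(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.01, 0.99, 500)
        y = (rng.random(500) < 0.3).astype(float)
        curve = fit_loess_curve(p, y, max_eval_points=50)
        assert len(curve.eval_points) <= 50

    def test_frozen_design_unit_counts_equal_full_fit(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.05, 0.95, 400)
        y = (rng.random(400) < p).astype(float)
        design = FrozenLoessDesign(p, y, max_eval_points=60)
        refit = design.refit(np.ones(400))
        assert np.allclose(refit, design.curve.fitted, atol=1e-10)


class TestEavgEmax:
    def test_identity_curve_gives_zero(self):
        pts = np.linspace(0.1, 0.9, 30)
        curve = SmoothedCurve(pts, pts.copy(), span=0.75, degree=1)
        assert eavg_emax(curve, pts) == (0.0, 0.0)

    def test_uniform_shift_gives_shift(self):
        pts = np.linspace(0.1, 0.8, 30)
        curve = SmoothedCurve(pts, pts + 0.1, span=0.75, degree=1)
        eavg, emax = eavg_emax(curve, pts)
        assert eavg == pytest.approx(0.1, abs=1e-12)
        assert emax == pytest.approx(0.1, abs=1e-12)

    def test_eavg_never_exceeds_emax(self, miscalibrated_sample):
        p, y = miscalibrated_sample
        m = moderate_calibration(p, y)
        assert m.eavg <= m.emax

    def test_eavg_matches_integrated_truth(self):
        """Large-n Eavg approaches E|c(P) - P| for the known true curve."""
        from scipy.integrate import quad
        from scipy.stats import norm
        a, b, mu, sigma = -1.0, 1.4, 0.0, 1.5
        p, y = make_scored_outcomes(a, b, 150_000, seed=11, mu=mu, sigma=sigma)
        # a narrow span at this n: smoothing bias shrinks, variance stays tiny
        m = moderate_calibration(p, y, span=0.2)
        integrand = lambda z: (abs(expit(a + b * z) - expit(z))
                               * norm.pdf(z, mu, sigma))
        truth, _ = quad(integrand, mu - 10 * sigma, mu + 10 * sigma)
        assert m.eavg == pytest.approx(truth, abs=0.01)
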