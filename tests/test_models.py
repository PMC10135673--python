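"""Response-model estimation: ML identities, recovery, selection, curves."""

import numpy as np
import pytest

from traitseg.errors import EstimationError, ValidationError
from traitseg.models import (
    backward_select,
    center_predictor,
    fit_linear,
    fit_negbin,
    residual_diagnostics,
    response_curve,
)


def _nb_draw(rng, mu, k):
    return rng.negative_binomial(k, k / (k + mu))


class TestCentering:
    def test_simple_and_constant_vectors(self):
        xc, m = center_predictor([1.0, 2.0, 3.0])
        np.testing.assert_allclose(xc, [-1, 0, 1])
        assert m == 2.0
        xc, m = center_predictor([4.0] * 5)
        np.testing.assert_allclose(xc, np.zeros(5))
        assert m == 4.0

    def test_mean_zero_for_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            xc, _ = center_predictor(rng.normal(3, 10, size=rng.integers(2, 200)))
            assert abs(xc.mean()) < 1e-12

    def test_empty_and_missing_rejected(self):
        with pytest.raises(ValidationError):
            center_predictor([])
        with pytest.raises(ValidationError):
            center_predictor([1.0, np.nan])


class TestNegativeBinomialFit:
    def test_intercept_only_recovers_sample_mean(self):
        rng = np.random.default_rng(3)
        y = _nb_draw(rng, np.full(200, 7.0), 2.0)
        fit = fit_negbin(y, np.zeros(200), form="intercept")
        assert np.exp(fit.coefficients[0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_matches_statsmodels_ml(self):
        """Same likelihood optimum as the reference NB2 implementation."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        x = rng.uniform(-1, 1, 300)
        y = _nb_draw(rng, np.exp(1.0 + 0.8 * x), 2.0)
        fit = fit_negbin(y, x, form="linear")
        ref = sm.NegativeBinomial(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params[:2], atol=1e-4)
        assert fit.k == pytest.approx(1.0 / ref.params[-1], rel=1e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_parameter_recovery_within_three_se(self):
        """beta estimates fall within 3 SE of the truth in ~99% of replicates."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.uniform(-1, 1, 500)
            y = _nb_draw(rng, np.exp(1.0 + 0.8 * x), 2.0)
            fit = fit_negbin(y, x, form="linear")
            se = np.sqrt(np.diag(fit.cov))
            ok = abs(fit.coefficients[0] - 1.0) < 3 * se[0] and abs(fit.coefficients[1] - 0.8) < 3 * se[1]
            hits += ok
        assert hits / reps >= 0.97

    def test_poisson_limit(self):
        """On equidispersed data k runs large and coefficients match Poisson ML."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        x = rng.uniform(-1, 1, 1000)
        y = rng.poisson(np.exp(1.2 + 0.5 * x))
        fit = fit_negbin(y, x, form="linear")
        assert fit.k > 1e3
        ref = sm.Poisson(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-3)

    def test_all_zero_response_advises_exclusion(self):
        with pytest.raises(EstimationError, match="sparsity"):
            fit_negbin(np.zeros(50, dtype=int), np.linspace(-1, 1, 50))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValidationError):
            fit_negbin(np.array([1.5, 2.0, 3.0, 1.0, 2.0]), np.linspace(-1, 1, 5))


class TestLinearFit:
    def test_exact_collinear_data(self):
        x = np.linspace(-2, 2, 30)
        y = 3.0 + 1.5 * x
        fit = fit_linear(y, x, form="linear")
        np.testing.assert_allclose(fit.coefficients, [3.0, 1.5], atol=1e-10)
        diag = residual_diagnostics(fit)
        np.testing.assert_allclose(diag["deviance_residual"], 0.0, atol=1e-10)

    def test_intercept_only_is_mean(self):
        rng = np.random.default_rng(1)
        y = rng.normal(5, 2, 100)
        fit = fit_linear(y, np.zeros(100), form="intercept")
        assert fit.coefficients[0] == pytest.approx(y.mean())

    def test_quadratic_recovery_within_three_se(self):
        rng = np.random.default_rng(21)
        hits, reps = 0, 200
        truth = np.array([1.0, -0.5, 0.8])
        for _ in range(reps):
            x = rng.uniform(-2, 2, 300)
            y = truth[0] + truth[1] * x + truth[2] * x**2 + rng.normal(0, 1, 300)
            fit = fit_linear(y, x, form="quadratic")
            se = np.sqrt(np.diag(fit.cov))
            hits += np.all(np.abs(fit.coefficients - truth) < 3 * se)
        assert hits / reps >= 0.97


class TestBackwardSelection:
    def test_strong_quadratic_retained(self):
        rng = np.random.default_rng(2)
        kept = 0
        for _ in range(40):
            x = rng.uniform(0, 10, 80)
            y = _nb_draw(rng, np.exp(1.0 + 0.3 * (x - 5) - 0.15 * (x - 5) ** 2), 2.0)
            fit = backward_select(y, x, "negative-binomial")
            kept += fit.form == "quadratic"
        assert kept / 40 >= 0.95

    def test_pure_noise_mostly_intercept_only(self):
        rng = np.random.default_rng(4)
        chosen = [
            backward_select(rng.normal(0, 1, 80), rng.uniform(0, 1, 80), "gaussian").form
            for _ in range(200)
        ]
        frac_intercept = np.mean([f == "intercept" for f in chosen])
        # two sequential 5% tests keep the null model ~90% of the time
        assert 0.84 <= frac_intercept <= 0.96

    def test_trace_consistent_with_selected_form(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 80)
        y = _nb_draw(rng, np.exp(0.5 + 0.25 * x), 2.0)
        fit = backward_select(y, x, "negative-binomial")
        steps = {t["term"]: t for t in fit.trace}
        if fit.form == "quadratic":
            assert steps["quadratic"]["kept"] and steps["quadratic"]["p_value"] < 0.05
        else:
            assert not steps["quadratic"]["kept"]
        if fit.form == "linear":
            assert steps["linear"]["kept"] and steps["linear"]["p_value"] < 0.05

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 5, 60)
        y = _nb_draw(rng, np.exp(1 + 0.4 * x), 2.0)
        a = backward_select(y, x, "negative-binomial")
        b = backward_select(y, x, "negative-binomial")
        assert a.form == b.form and a.trace == b.trace
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_likelihood_monotone_in_model_complexity(self):
        rng = np.random.default_rng(9)
        for family in ("negative-binomial", "gaussian"):
            for _ in range(5):
                x = rng.uniform(0, 4, 70)
                xc, _ = center_predictor(x)
                if family == "gaussian":
                    y = rng.normal(0, 1, 70)
                    fits = [fit_linear(y, xc, f) for f in ("intercept", "linear", "quadratic")]
                else:
                    y = _nb_draw(rng, np.full(70, 4.0), 2.0)
                    fits = [fit_negbin(y, xc, f) for f in ("intercept", "linear", "quadratic")]
                assert fits[0].loglik <= fits[1].loglik + 1e-6
                assert fits[1].loglik <= fits[2].loglik + 1e-6


class TestResponseCurve:
    def test_intercept_only_constant_at_sample_mean(self):
        rng = np.random.default_rng(10)
        y = _nb_draw(rng, np.full(100, 6.0), 2.0)
        fit = fit_negbin(y, np.zeros(100), form="intercept")
        mean, flags = response_curve(fit, np.linspace(0, 1, 7))
        np.testing.assert_allclose(mean, y.mean(), rtol=1e-6)

    def test_closed_form_evaluation(self):
        fit = fit_negbin(
            np.array([1, 2, 3, 4, 5, 6]), np.array([-1.0, -0.5, 0.0, 0.2, 0.5, 1.0]), "linear"
        )
        fit.coefficients = np.array([1.0, 0.5])
        fit.center = 0.0
        mean, _ = response_curve(fit, np.array([2.0]))
        assert mean[0] == pytest.approx(np.exp(2.0))

    def test_matches_scalar_link_formula_on_random_grid(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 10, 120)
        y = _nb_draw(rng, np.exp(1 + 0.2 * x), 2.0)
        fit = backward_select(y, x, "negative-binomial")
        grid = rng.uniform(0, 10, 10)
        mean, _ = response_curve(fit, grid)
        for g, m in zip(grid, mean):
            eta = sum(
                b * (g - fit.center) ** p for p, b in enumerate(fit.coefficients)
            )
            assert m == pytest.approx(np.exp(eta), rel=1e-10)

    def test_extrapolation_flags(self):
        x = np.linspace(0, 1, 30)
        fit = fit_linear(2 * x + 1, x, "linear")
        _, flags = response_curve(fit, np.array([-0.5, 0.5, 1.5]))
        np.testing.assert_array_equal(flags, [True, False, True])

    def test_centering_leaves_original_scale_curve_unchanged(self):
        """Fitting on centred vs raw predictor gives identical mean curves."""
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 10, 150)
        y = _nb_draw(rng, np.exp(0.5 + 0.25 * x), 2.0)
        xc, m = center_predictor(x)
        fit_centred = fit_negbin(y, xc, "linear", center=m)
        fit_raw = fit_negbin(y, x, "linear", center=0.0)
        grid = np.linspace(0, 10, 25)
        mean_c, _ = response_curve(fit_centred, grid)
        mean_r, _ = response_curve(fit_raw, grid)
        np.testing.assert_allclose(mean_c, mean_r, rtol=1e-6)


class TestDiagnostics:
    def test_residual_count_matches_observations(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 5, 90)
        y = _nb_draw(rng, np.exp(1 + 0.3 * x), 2.0)
        diag = residual_diagnostics(fit_negbin(y, x, "linear"))
        assert len(diag) == 90
        assert {"fitted", "deviance_residual"} <= set(diag.columns)

    def test_nb_deviance_residuals_centre_near_zero(self):
        # moderate dispersion/mean: deviance residuals of well-specified NB
        # data centre near zero (their small negative bias grows with skew)
        rng = np.random.default_rng(15)
        x = rng.uniform(-1, 1, 500)
        y = _nb_draw(rng, np.exp(2.0 + 0.6 * x), 5.0)
        diag = residual_diagnostics(fit_negbin(y, x, "linear"))
        assert abs(diag.attrs["mean"]) < 0.2

    def test_nb_deviance_residuals_match_reference_formula(self):
        """Deviance residuals agree with an independent scalar evaluation."""
        rng = np.random.default_rng(16)
        x = rng.uniform(-1, 1, 80)
        y = _nb_draw(rng, np.exp(1.5 + 0.6 * x), 2.0)
        fit = fit_negbin(y, x, "linear")
        diag = residual_diagnostics(fit)
        k = fit.k
        for yi, mui, ri in zip(y, fit.mu, diag["deviance_residual"]):
            term = yi * np.log(yi / mui) if yi > 0 else 0.0
            dev = 2 * (term - (yi + k) * np.log((yi + k) / (mui + k)))
            assert ri == pytest.approx(np.sign(yi - mui) * np.sqrt(max(dev, 0)), abs=1e-10)
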