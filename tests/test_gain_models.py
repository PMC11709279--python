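import numpy as np
import pytest
from scipy.integrate import quad

from lamigain.errors import AnalysisValidationError, FitError, UndefinedStatisticError
from lamigain.gain_models import (
    NonlinearityParams,
    adjusted_r2,
    aic_bic,
    contribution_decomposition,
    fit_gain_model,
    gain_dsi,
    power_law,
    relu,
    response_ratio_tuning,
    threshold_linear,
)
from lamigain.synthetic_data import make_ground_truth, simulate_probe

from conftest import group_masks


class TestThresholdLinear:
    def test_value_at_threshold(self):
        p = NonlinearityParams("threshold_linear", A=3.0, g0=2.0, sigma=1.5)
        # erf(0) = 0, so f(g0) = A·sigma/sqrt(2*pi)
        expect = 3.0 * 1.5 / np.sqrt(2 * np.pi)
        assert threshold_linear(2.0, p) == pytest.approx(expect, rel=1e-12)

    def test_linear_asymptote_far_above_threshold(self):
        p = NonlinearityParams("threshold_linear", A=2.0, g0=1.0, sigma=0.5)
        g = 1.0 + 10 * 0.5
        assert threshold_linear(g, p) == pytest.approx(2.0 * (g - 1.0), rel=1e-10)

    def test_equals_gaussian_expectation_quadrature(self):
        """f(g) is exactly E[A·max(g + eps − g0, 0)], eps ~ N(0, sigma^2)."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            A, g0, sigma = rng.uniform(0.5, 4), rng.uniform(-2, 2), rng.uniform(0.3, 2)
            g = rng.uniform(-5, 5)
            p = NonlinearityParams("threshold_linear", A=A, g0=g0, sigma=sigma)

            def integrand(e):
                return (
                    A
                    * max(g + e - g0, 0.0)
                    * np.exp(-(e**2) / (2 * sigma**2))
                    / (sigma * np.sqrt(2 * np.pi))
                )

            expect, _ = quad(integrand, -10 * sigma, 10 * sigma)
            assert threshold_linear(g, p) == pytest.approx(expect, abs=1e-8)

    def test_sigma_to_zero_limit_is_relu(self):
        # pointwise limit holds for g != g0; the grid stays clear of the
        # threshold by many multiples of sigma
        grid = np.linspace(-5, 5, 101)
        p = NonlinearityParams("threshold_linear", A=1.7, g0=0.37, sigma=1e-4)
        np.testing.assert_allclose(
            threshold_linear(grid, p), 1.7 * np.maximum(grid - 0.37, 0.0), atol=1e-6
        )

    def test_invalid_sigma_rejected(self):
        with pytest.raises(AnalysisValidationError):
            NonlinearityParams("threshold_linear", A=1.0, g0=0.0, sigma=0.0)


class TestPowerLaw:
    def test_below_threshold_is_zero(self):
        p = NonlinearityParams("power_law", A=2.0, g0=1.0, n=2.0)
        assert power_law(0.5, p) == 0.0

    def test_exponent_one_reduces_to_relu(self):
        p1 = NonlinearityParams("power_law", A=2.0, g0=1.0, n=1.0)
        pr = NonlinearityParams("relu", A=2.0, g0=1.0)
        g = np.linspace(-3, 5, 30)
        np.testing.assert_allclose(power_law(g, p1), relu(g, pr))

    def test_arithmetic_example(self):
        p = NonlinearityParams("power_law", A=2.0, g0=1.0, n=2.0)
        assert power_law(3.0, p) == pytest.approx(8.0)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(AnalysisValidationError):
            NonlinearityParams("power_law", A=1.0, g0=0.0, n=0.0)


class TestAdjustedR2:
    def test_perfect_fit_is_one(self):
        y = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        assert adjusted_r2(y, y, n_param=3) == pytest.approx(1.0)

    def test_constant_fit_matches_hand_arithmetic(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        f = np.full(5, 3.0)
        # numerator 2*sum((f-y)^2) = 20; denominator 0 + sum((y-3)^2) = 10
        expect = 1.0 - (4 / 3) * (20.0 / 10.0)
        assert adjusted_r2(f, y, n_param=2) == pytest.approx(expect)

    def test_extra_parameter_strictly_lowers_score(self):
        rng = np.random.default_rng(10)
        y = rng.normal(10, 2, 40)
        f = y + rng.normal(0, 0.5, 40)
        assert adjusted_r2(f, y, n_param=4) < adjusted_r2(f, y, n_param=3)

    def test_aic_bic_penalties(self):
        a3, b3 = aic_bic(10.0, 100, 3)
        a5, b5 = aic_bic(10.0, 100, 5)
        assert a5 - a3 == pytest.approx(4.0)
        assert b5 - b3 == pytest.approx(2 * np.log(100))


def _layer_rates(ds):
    from lamigain.data_model_io import layer_averaged_rates

    mask_in, mask_out = group_masks(ds.layer_labels)
    return (
        layer_averaged_rates(ds.table, np.flatnonzero(mask_in)),
        layer_averaged_rates(ds.table, np.flatnonzero(mask_out)),
    )


class TestFitGainModel:
    def test_forward_model_refit_is_self_consistent(self):
        """Trials generated by the tuned-gain model refit to J ~ 0 and the
        planted gain curve (up to the scale normalization)."""
        truth = make_ground_truth({"output_noise_scale": 0.0}, seed=51)
        ds = simulate_probe(truth, seed=52, with_psth=False)
        ir, orr = _layer_rates(ds)
        fit = fit_gain_model(ir, orr, model="II", directions=truth.directions,
                             seeds=range(6))
        assert fit.objective_J < 1e-8
        assert fit.adj_r2 > 0.999
        assert gain_dsi(fit) == pytest.approx(truth.gain_dsi, abs=1e-3)
        true_w = truth.gain_curve / truth.gain_curve[:-1].mean()
        np.testing.assert_allclose(fit.w, true_w, atol=1e-4)

    def test_identity_transmission_fits_model_one(self):
        truth = make_ground_truth(
            {"gain_mode": "untuned", "gain_base": 1.0,
             "nonlinearity": {"family": "relu", "A": 1.0, "g0": 0.0},
             "noise_model": {"kind": "none"}, "output_noise_scale": 0.0},
            seed=53,
        )
        ds = simulate_probe(truth, seed=54, with_psth=False)
        ir, orr = _layer_rates(ds)
        fit = fit_gain_model(ir, orr, model="I", family="relu",
                             directions=truth.directions, seeds=range(4))
        # degenerate noise-free input: every rep identical, so pairing is exact
        assert fit.objective_J == pytest.approx(0.0, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_model_nesting_objective(self):
        """Model I is a constrained Model II, so J(II) <= J(I)."""
        truth = make_ground_truth({}, seed=55)
        ds = simulate_probe(truth, seed=56, with_psth=False)
        ir, orr = _layer_rates(ds)
        f1 = fit_gain_model(ir, orr, model="I", directions=truth.directions,
                            seeds=range(4))
        f2 = fit_gain_model(ir, orr, model="II", directions=truth.directions,
                            seeds=range(4))
        assert f2.objective_J <= f1.objective_J + 1e-9
        assert f2.adj_r2 > f1.adj_r2

    def test_suppression_models_fit_their_own_forward_pass(self):
        rng = np.random.default_rng(57)
        n_cond, n_rep = 13, 12
        x = rng.uniform(5, 30, (n_cond, n_rep))
        w = np.append(1.0 + 0.3 * np.cos(np.deg2rad(np.arange(12) * 30.0)), 0.7)
        y3 = np.maximum(w[:, None] * x - 4.0, 0.0)
        f3 = fit_gain_model(x, y3, model="III", seeds=range(4))
        assert f3.objective_J < 1e-8
        np.testing.assert_allclose(f3.w, w, atol=1e-4)
        np.testing.assert_allclose(f3.T, 4.0, atol=1e-4)
        t = np.append(rng.uniform(1, 5, 12), 6.0)
        y4 = np.maximum(0.9 * x - t[:, None], 0.0)
        f4 = fit_gain_model(x, y4, model="IV", seeds=range(4))
        assert f4.objective_J < 1e-8
        np.testing.assert_allclose(f4.w, 0.9, atol=1e-4)

    def test_underdetermined_fit_rejected(self):
        x = np.ones((13, 2))
        with pytest.raises(FitError):
            fit_gain_model(x[:, :1].repeat(2, axis=1) * 0.0, x, model="II")


class TestContributionDecomposition:
    def test_zero_nonlinearity_contribution(self):
        cn, cg = contribution_decomposition(0.2, 0.5, 0.2, 0.4)
        assert cn == pytest.approx(0.0)

    def test_endpoint_additivity(self):
        cn, cg = contribution_decomposition(0.2, 0.5, 0.2, 0.5)
        assert (cn, cg) == (pytest.approx(0.0), pytest.approx(1.0))

    def test_arithmetic_example(self):
        cn, cg = contribution_decomposition(0.2, 0.5, 0.29, 0.47)
        assert cn == pytest.approx(0.30)
        assert cg == pytest.approx(0.60)

    def test_additivity_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            di, do, m1, m2 = rng.uniform(0, 1, 4)
            if abs(do - di) < 1e-6:
                continue
            cn, cg = contribution_decomposition(di, do, m1, m2)
            assert cn + cg == pytest.approx((m2 - di) / (do - di))

    def test_zero_denominator_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            contribution_decomposition(0.3, 0.3, 0.3, 0.3)


class TestResponseRatio:
    directions = np.arange(12) * 30.0

    def test_identity_gives_unit_ratio(self):
        means = np.append(np.full(12, 10.0), 5.0)
        rr = response_ratio_tuning(means, means, self.directions, theta_pref=90.0)
        np.testing.assert_allclose(rr.ratio, 1.0)
        assert rr.ratio_blank == pytest.approx(1.0)

    def test_alignment_maps_preferred_to_ninety(self):
        pref = 270.0
        out = np.append(
            10.0 + 5.0 * np.cos(np.deg2rad(self.directions - pref)), 5.0
        )
        inp = np.append(np.full(12, 10.0), 5.0)
        rr = response_ratio_tuning(inp, out, self.directions, theta_pref=pref)
        peak_aligned = rr.aligned_directions[np.argmax(rr.ratio)]
        assert peak_aligned == pytest.approx(90.0)
        assert rr.ratio_pref == pytest.approx(1.5)
        assert rr.ratio_null == pytest.approx(0.5)

    def test_tuned_gain_probe_ratio_peaks_at_preferred(self):
        truth = make_ground_truth({}, seed=61)
        ds = simulate_probe(truth, seed=62, with_psth=False)
        ir, orr = _layer_rates(ds)
        rr = response_ratio_tuning(
            np.nanmean(ir, axis=1), np.nanmean(orr, axis=1),
            truth.directions, truth.theta_pref,
        )
        assert rr.ratio_pref > rr.ratio_null
        assert rr.ratio_pref > rr.ratio_blank
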