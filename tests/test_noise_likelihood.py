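import numpy as np
import pytest
import scipy.integrate
import scipy.optimize
import scipy.stats

from gradmech.noise_likelihood import (
    NoiseModel,
    empirical_snr,
    lognormal_pdf,
    mixture_pdf,
    nll_direct,
    nll_filtered,
    nll_integrated,
    outlier_pdf,
    outlier_responsibility,
    residuals,
    sample_noise,
)


class TestDensities:
    def test_lognormal_peak_value(self):
        # at y_m = y the exponent vanishes
        assert lognormal_pdf(1.0, 1.0, 0.5) == pytest.approx(
            1.0 / (np.sqrt(2 * np.pi) * 0.5), rel=1e-12
        )

    def test_lognormal_matches_scipy_change_of_variables(self):
        rng = np.random.default_rng(0)
        y_m = rng.lognormal(1.0, 0.7, 50)
        y, sigma = 2.3, 0.4
        ours = lognormal_pdf(y_m, y, sigma)
        ref = scipy.stats.lognorm.pdf(y_m, s=sigma, scale=y)
        assert np.allclose(ours, ref, rtol=1e-12)

    @pytest.mark.parametrize(
        "density,kw",
        [
            (lognormal_pdf, dict(sigma=0.3)),
            (lognormal_pdf, dict(sigma=1.2)),
            (outlier_pdf, dict(mu_o=0.8, sigma_o=0.5)),
            (outlier_pdf, dict(mu_o=-0.5, sigma_o=1.5)),
        ],
    )
    def test_unit_normalization_by_quadrature(self, density, kw):
        y = 3.0
        total, err = scipy.integrate.quad(
            lambda z: density(z, y, **kw), 0, np.inf, limit=200
        )
        assert abs(total - 1.0) < 1e-8

    def test_mixture_normalization_by_quadrature(self):
        noise = NoiseModel(sigma=0.3, w_o=0.35, mu_o=1.0, sigma_o=0.8)
        total, _ = scipy.integrate.quad(
            lambda z: mixture_pdf(z, 2.0, noise), 0, np.inf, limit=200
        )
        assert abs(total - 1.0) < 1e-8

    def test_outlier_reduces_to_lognormal(self):
        y_m = np.array([0.5, 1.0, 3.0])
        assert np.allclose(
            outlier_pdf(y_m, 1.5, 0.0, 0.4), lognormal_pdf(y_m, 1.5, 0.4)
        )

    def test_outlier_mode_shifts_by_exp_mu(self):
        y, sigma_o = 2.0, 0.3
        def neg(mu_o):
            return lambda z: -outlier_pdf(z[0], y, mu_o, sigma_o)
        m0 = scipy.optimize.minimize(neg(0.0), [y], bounds=[(1e-3, 50)]).x[0]
        m1 = scipy.optimize.minimize(neg(0.7), [m0 * np.exp(0.7)], bounds=[(1e-3, 50)]).x[0]
        assert m1 / m0 == pytest.approx(np.exp(0.7), rel=1e-4)

    def test_mixture_endpoints_and_interior(self):
        y_m = np.array([0.7, 2.0, 9.0])
        y = 1.8
        n0 = NoiseModel(sigma=0.25, w_o=0.0, mu_o=1.0, sigma_o=0.6)
        n1 = NoiseModel(sigma=0.25, w_o=1.0, mu_o=1.0, sigma_o=0.6)
        nm = NoiseModel(sigma=0.25, w_o=0.3, mu_o=1.0, sigma_o=0.6)
        assert np.array_equal(mixture_pdf(y_m, y, n0), lognormal_pdf(y_m, y, 0.25))
        assert np.array_equal(mixture_pdf(y_m, y, n1), outlier_pdf(y_m, y, 1.0, 0.6))
        expected = 0.7 * lognormal_pdf(y_m, y, 0.25) + 0.3 * outlier_pdf(y_m, y, 1.0, 0.6)
        assert np.allclose(mixture_pdf(y_m, y, nm), expected, rtol=1e-12)

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            lognormal_pdf(-1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            lognormal_pdf(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            NoiseModel(sigma=0.3, w_o=1.5)


class TestObjectives:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.model = rng.uniform(1.0, 5.0, (6, 6))
        self.data = self.model * rng.lognormal(0, 0.2, (6, 6))

    def test_single_pixel_direct_value(self):
        sigma, y = 0.4, 2.5
        val = nll_direct(np.array([[y]]), np.array([[y]]), sigma)
        assert val == pytest.approx(np.log(np.sqrt(2 * np.pi) * sigma * y))

    def test_direct_equals_per_pixel_sum(self):
        sigma = 0.3
        expected = -np.log(lognormal_pdf(self.data, self.model, sigma)).sum()
        assert nll_direct(self.data, self.model, sigma) == pytest.approx(expected)

    def test_mask_excludes_pixels(self):
        mask = np.ones((6, 6), dtype=bool)
        mask[0, 0] = False
        full = nll_direct(self.data, self.model, 0.3, mask)
        data2 = self.data.copy()
        data2[0, 0] = 1e6  # excluded pixel must not matter
        assert nll_direct(data2, self.model, 0.3, mask) == pytest.approx(full)

    def test_filtered_with_empty_set_equals_direct(self):
        f = np.zeros((6, 6), dtype=bool)
        assert nll_filtered(self.data, self.model, 0.3, f) == pytest.approx(
            nll_direct(self.data, self.model, 0.3)
        )

    def test_filtered_removes_exactly_that_term(self):
        f = np.zeros((6, 6), dtype=bool)
        f[2, 3] = True
        term = -np.log(lognormal_pdf(self.data[2, 3], self.model[2, 3], 0.3))
        assert nll_direct(self.data, self.model, 0.3) - nll_filtered(
            self.data, self.model, 0.3, f
        ) == pytest.approx(term)

    def test_filtering_everything_raises(self):
        with pytest.raises(ValueError):
            nll_filtered(self.data, self.model, 0.3, np.ones((6, 6), dtype=bool))

    def test_integrated_with_zero_weight_equals_direct(self):
        noise = NoiseModel(sigma=0.3, w_o=0.0)
        assert nll_integrated(self.data, self.model, noise) == pytest.approx(
            nll_direct(self.data, self.model, 0.3)
        )

    def test_integrated_matches_brute_force(self):
        noise = NoiseModel(sigma=0.3, w_o=0.2, mu_o=0.9, sigma_o=0.7)
        expected = -np.log(mixture_pdf(self.data, self.model, noise)).sum()
        assert nll_integrated(self.data, self.model, noise) == pytest.approx(expected)

    def test_optimized_mixture_no_worse_than_direct(self):
        # the direct model is the w_o -> 0 boundary of the mixture family
        sigma = 0.3
        direct = nll_direct(self.data, self.model, sigma)

        def f(x):
            w, mu, ls = x
            return nll_integrated(
                self.data, self.model, NoiseModel(sigma, w, mu, np.exp(ls))
            )

        res = scipy.optimize.minimize(
            f, [0.01, 0.0, 0.0], bounds=[(1e-9, 1 - 1e-9), (-2, 3), (-3, 2)]
        )
        assert res.fun <= direct + 1e-6

    def test_continuity_in_outlier_weight(self):
        sigma = 0.3
        base = NoiseModel(sigma, 0.0, 0.9, 0.7)
        eps = NoiseModel(sigma, 1e-9, 0.9, 0.7)
        assert nll_integrated(self.data, self.model, eps) == pytest.approx(
            nll_integrated(self.data, self.model, base), rel=1e-6
        )


class TestResponsibilityAndResiduals:
    def test_zero_weight_gives_zero_responsibility(self):
        r = outlier_responsibility(np.array([1.0, 5.0]), 2.0, NoiseModel(0.3))
        assert np.all(r == 0)

    def test_equal_components_give_weight(self):
        noise = NoiseModel(sigma=0.4, w_o=0.25, mu_o=0.0, sigma_o=0.4)
        r = outlier_responsibility(np.array([0.5, 2.0, 7.0]), 2.0, noise)
        assert np.allclose(r, 0.25)

    def test_responsibility_increasing_in_brightness(self):
        noise = NoiseModel(sigma=0.3, w_o=0.2, mu_o=1.5, sigma_o=0.3)
        y_m = np.linspace(0.5, 30.0, 200)
        r = outlier_responsibility(y_m, 2.0, noise)
        assert np.all(np.diff(r) >= -1e-12)

    def test_residual_values(self):
        sigma = 0.3
        y = np.array([[2.0]])
        assert residuals(y, y, sigma)[0] == 0.0
        assert residuals(y * np.exp(sigma), y, sigma)[0] == pytest.approx(1.0)

    def test_residuals_standardized_under_true_model(self):
        rng = np.random.default_rng(5)
        model = np.full((400, 400), 3.0)
        data = sample_noise(model, NoiseModel(0.25), seed=rng)
        r = residuals(data, model, 0.25)
        assert abs(r.mean()) < 0.01 and abs(r.std() - 1.0) < 0.01


class TestSampling:
    def test_seeded_reproducibility(self):
        model = np.full((10, 10), 2.0)
        a = sample_noise(model, NoiseModel(0.3), seed=42)
        b = sample_noise(model, NoiseModel(0.3), seed=42)
        assert np.array_equal(a, b)

    def test_small_sigma_limit(self):
        model = np.full((20, 20), 5.0)
        noisy = sample_noise(model, NoiseModel(1e-9), seed=0)
        assert np.allclose(noisy, model, rtol=1e-7)

    def test_log_ratio_std_matches_sigma(self):
        model = np.full((400, 250), 1.7)
        noisy = sample_noise(model, NoiseModel(0.2), seed=3)
        assert np.log(noisy / model).std() == pytest.approx(0.2, rel=0.01)

    def test_snr_matches_closed_form_on_constant_image(self):
        noise = NoiseModel(0.18)
        model = np.full((600, 600), 4.0)
        noisy = sample_noise(model, noise, seed=9)
        # closed form 1/sqrt(e^{sigma^2}-1) holds up to the mean-shift term
        assert empirical_snr(model, noisy) == pytest.approx(noise.snr, rel=0.02)
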