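import numpy as np
import pytest
import scipy.stats

from gradmech.forward_model import ReducedParameters
from gradmech.inference import (
    Param,
    ParameterSpace,
    WholeImageObjective,
    bic,
    compare_models,
    fit_approach,
    lhs_starts,
    multistart_fit,
    paired_onesided_test,
    profile_likelihood,
    profile_product,
)
from gradmech.noise_likelihood import NoiseModel
from gradmech.synthetic_data import default_scene, generate_artificial_dataset


def linear_space(n, lo=-3.0, hi=3.0):
    return ParameterSpace([Param(f"x{i}", lo, hi, "linear") for i in range(n)])


class TestParameterTransforms:
    @pytest.mark.parametrize(
        "param,value",
        [
            (Param("a", 1e-2, 1e2, "log10"), 3.7),
            (Param("w", 1e-6, 1 - 1e-6, "logit"), 0.42),
            (Param("m", -2.0, 5.0, "linear"), 1.3),
        ],
    )
    def test_round_trip(self, param, value):
        assert param.to_external(param.to_internal(value)) == pytest.approx(value)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            Param("a", 2.0, 2.0, "linear")

    def test_space_dict_round_trip(self):
        space = ParameterSpace(
            [Param("a", 1e-2, 1e2, "log10"), Param("w", 1e-6, 1 - 1e-6, "logit")]
        )
        values = {"a": 0.5, "w": 0.9}
        out = space.to_external(space.to_internal(values))
        assert out["a"] == pytest.approx(0.5)
        assert out["w"] == pytest.approx(0.9)


class TestLhsStarts:
    def test_single_start_inside_box(self):
        x = lhs_starts(linear_space(3), 1, seed=0)
        assert x.shape == (1, 3)
        assert np.all(x >= -3) and np.all(x <= 3)

    def test_per_dimension_stratification(self):
        n = 16
        x = lhs_starts(linear_space(4), n, seed=1)
        edges = np.linspace(-3, 3, n + 1)
        for d in range(4):
            strata = np.digitize(np.sort(x[:, d]), edges) - 1
            assert np.array_equal(strata, np.arange(n))

    def test_seeded_reproducibility(self):
        a = lhs_starts(linear_space(2), 5, seed=3)
        b = lhs_starts(linear_space(2), 5, seed=3)
        assert np.array_equal(a, b)


class TestMultistart:
    def test_convex_quadratic_flat_ladder(self):
        target = np.array([0.7, -1.2])

        def f(x):
            return float(np.sum((x - target) ** 2))

        fit = multistart_fit(f, linear_space(2), n_starts=8, seed=0)
        assert np.allclose(fit.ladder, fit.ladder[0], atol=1e-8)
        assert np.allclose(fit.best_internal, target, atol=1e-4)

    def test_ladder_sorted(self):
        def f(x):
            return float(np.cos(3 * x[0]) + x[0] ** 2 / 10)

        fit = multistart_fit(f, linear_space(1, -8, 8), n_starts=10, seed=1)
        assert np.all(np.diff(fit.ladder) >= 0)

    def test_multimodal_matches_grid_search(self):
        # banana-shaped valley with a unique global optimum
        def f(x):
            return float((1 - x[0]) ** 2 + 5 * (x[1] - x[0] ** 2) ** 2)

        space = linear_space(2, -2.0, 2.0)
        fit = multistart_fit(f, space, n_starts=20, seed=2)
        g = np.linspace(-2, 2, 201)
        vals = np.array([[f(np.array([a, b])) for b in g] for a in g])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        assert fit.best_nll <= vals[i, j] + 1e-6
        assert np.allclose(fit.best_internal, [1.0, 1.0], atol=1e-3)

    def test_best_no_worse_than_truth_on_synthetic(self):
        grid, vessels = default_scene(0, (32, 32), 2)
        ds = generate_artificial_dataset(grid, vessels, seed=1)
        obj = WholeImageObjective(ds.noisy, grid, vessels, approach="direct")
        fit = multistart_fit(obj, obj.space, n_starts=5, seed=0)
        truth = obj.space.to_internal(
            {
                "d_over_gamma": ds.params.d_over_gamma,
                "rho": ds.params.rho,
                "s_s0": ds.params.s_s0,
                "bg": ds.params.bg,
                "sigma": ds.noise.sigma,
            }
        )
        assert fit.best_nll <= obj(truth) + 1e-9


class TestProfileLikelihood:
    def test_gaussian_mean_interval_closed_form(self):
        rng = np.random.default_rng(0)
        sigma_known, n = 2.0, 40
        x = rng.normal(1.0, sigma_known, n)

        def nll(theta):
            return float(np.sum((x - theta[0]) ** 2) / (2 * sigma_known**2))

        space = ParameterSpace([Param("mu", -10.0, 10.0, "linear")])
        fit = multistart_fit(nll, space, n_starts=4, seed=0)
        # profiling the only parameter = scanning the nll itself
        prof = profile_likelihood(nll, space, fit, "mu", levels=(0.90,))
        lo, hi = prof.intervals[0.90]
        half = 1.6449 * sigma_known / np.sqrt(n)
        assert lo == pytest.approx(x.mean() - half, abs=0.01)
        assert hi == pytest.approx(x.mean() + half, abs=0.01)

    def test_profile_minimum_equals_best_nll(self):
        grid, vessels = default_scene(0, (32, 32), 2)
        ds = generate_artificial_dataset(grid, vessels, seed=2)
        obj = WholeImageObjective(ds.noisy, grid, vessels, approach="direct")
        fit = multistart_fit(obj, obj.space, n_starts=5, seed=0)
        prof = profile_likelihood(obj, obj.space, fit, "bg", levels=(0.90,))
        assert prof.profile_nll.min() == pytest.approx(fit.best_nll, abs=1e-6)

    def test_intervals_nested_across_levels(self):
        grid, vessels = default_scene(0, (32, 32), 2)
        ds = generate_artificial_dataset(grid, vessels, seed=2)
        obj = WholeImageObjective(ds.noisy, grid, vessels, approach="direct")
        fit = multistart_fit(obj, obj.space, n_starts=5, seed=0)
        prof = profile_likelihood(obj, obj.space, fit, "sigma")
        l75, l90, l99 = (prof.intervals[c] for c in (0.75, 0.90, 0.99))
        assert l99[0] <= l90[0] <= l75[0] <= l75[1] <= l90[1] <= l99[1]

    def test_product_profile_consistent_with_objective(self):
        grid, vessels = default_scene(0, (32, 32), 2)
        ds = generate_artificial_dataset(grid, vessels, seed=2)
        obj = WholeImageObjective(ds.noisy, grid, vessels, approach="direct")
        fit = multistart_fit(obj, obj.space, n_starts=5, seed=0)
        prof = profile_product(obj, obj.space, fit, "rho", "s_s0", levels=(0.90,))
        lo, hi = prof.intervals[0.90]
        est = fit.best_external
        assert lo < est["rho"] * est["s_s0"] < hi


class TestBicAndComparison:
    def test_worked_example(self):
        assert bic(500.0, 6, 10_000) == pytest.approx(1055.2620, abs=1e-3)

    def test_zero_parameters(self):
        assert bic(123.0, 0, 50) == 246.0

    def test_monotone_in_nll_and_complexity(self):
        assert bic(10, 3, 100) < bic(11, 3, 100) < bic(11, 4, 100)

    def _fake_fit(self, nll, n_theta, n_data, dataset_id, approach="direct"):
        from gradmech.inference import ApproachFit, FitResult

        space = linear_space(n_theta)
        fr = FitResult(
            space=space,
            starts=np.zeros((1, n_theta)),
            solutions=np.zeros((1, n_theta)),
            nlls=np.array([nll]),
            converged=np.array([True]),
        )
        return ApproachFit(
            fit=fr, objective=None, space=space, approach=approach,
            hypothesis=1, n_data=n_data, dataset_id=dataset_id,
        )

    def test_single_model_delta_zero(self):
        cmp_ = compare_models([self._fake_fit(100, 2, 50, "d")], ["only"])
        assert cmp_.table.loc["only", "delta_bic"] == 0.0

    def test_equal_nll_delta_is_log_n(self):
        fits = [self._fake_fit(100, 2, 50, "d"), self._fake_fit(100, 3, 50, "d")]
        cmp_ = compare_models(fits, ["small", "big"])
        assert cmp_.table.loc["big", "delta_bic"] == pytest.approx(np.log(50))

    def test_cross_approach_comparison_refused(self):
        fits = [
            self._fake_fit(100, 2, 50, "d", "direct"),
            self._fake_fit(90, 2, 50, "d", "integrated"),
        ]
        with pytest.raises(ValueError, match="approach"):
            compare_models(fits, ["a", "b"])

    def test_different_datasets_refused(self):
        fits = [self._fake_fit(100, 2, 50, "d1"), self._fake_fit(90, 2, 50, "d2")]
        with pytest.raises(ValueError, match="datasets"):
            compare_models(fits, ["a", "b"])


class TestPairedTest:
    def test_textbook_example(self):
        p = paired_onesided_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        d = np.array([1.0, 2.0, 3.0])
        t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(scipy.stats.t.sf(t, 2), abs=1e-12)
        assert p == pytest.approx(0.0371, abs=2e-3)

    def test_identical_samples_give_half(self):
        a = [1.0, 2.0, 3.0]
        assert paired_onesided_test(a, a) == 0.5

    def test_degenerate_constant_shift(self):
        assert paired_onesided_test([2.0, 2.0, 2.0], [1.0, 1.0, 1.0]) == 0.0
        assert paired_onesided_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0]) == 1.0

    def test_one_sided_duality(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        assert paired_onesided_test(a, b) + paired_onesided_test(b, a) == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 12), rng.normal(0, 1, 12)
        ref = scipy.stats.ttest_rel(a, b, alternative="greater").pvalue
        assert paired_onesided_test(a, b) == pytest.approx(ref, rel=1e-10)


class TestFitApproach:
    def test_filtered_without_detections_equals_direct(self):
        grid, vessels = default_scene(0, (32, 32), 2)
        ds = generate_artificial_dataset(grid, vessels, n_spots=0, seed=4)
        direct = fit_approach(ds.noisy, grid, vessels, "direct", n_starts=4, seed=1)
        filtered = fit_approach(ds.noisy, grid, vessels, "filtered", n_starts=4, seed=1)
        if not filtered.filter_mask.any():
            assert filtered.fit.best_nll == pytest.approx(direct.fit.best_nll)
        else:  # a handful of false detections: objectives differ by those terms
            assert filtered.n_data < direct.n_data

    def test_integrated_on_spotless_data_matches_direct(self):
        grid, vessels = default_scene(1, (32, 32), 2)
        ds = generate_artificial_dataset(grid, vessels, n_spots=0, seed=5)
        direct = fit_approach(ds.noisy, grid, vessels, "direct", n_starts=8, seed=1)
        integ = fit_approach(ds.noisy, grid, vessels, "integrated", n_starts=8, seed=1)
        assert integ.fit.best_nll <= direct.fit.best_nll + 1e-6
        de, ie = direct.estimate, integ.estimate
        # outlier weight collapses and the mechanistic estimates agree
        assert ie["w_o"] < 0.05
        for k in ("d_over_gamma", "rho", "s_s0", "bg"):
            assert np.log10(ie[k] / de[k]) == pytest.approx(0.0, abs=0.1)

    def test_boundary_margin_reduces_data_count(self):
        grid, vessels = default_scene(0, (32, 32), 2)
        ds = generate_artificial_dataset(grid, vessels, seed=6)
        full = fit_approach(ds.noisy, grid, vessels, "direct", n_starts=2, seed=1)
        trimmed = fit_approach(
            ds.noisy, grid, vessels, "direct", n_starts=2, seed=1, boundary_depth=8.0
        )
        assert trimmed.n_data < full.n_data


class TestJointFit:
    def test_shared_parameters_with_per_image_scaling(self):
        from gradmech.forward_model import ReducedParameters
        from gradmech.inference import fit_images_jointly
        from gradmech.noise_likelihood import NoiseModel
        from gradmech.synthetic_data import DEFAULT_SIGMA

        base = ReducedParameters(64.0, 2.0, 100.0, 40.0)
        c2 = 2.5  # second image recorded with a 2.5x brighter staining
        scaled = ReducedParameters(64.0, 2.0, c2 * 100.0, c2 * 40.0)
        datas, grids, vessels_list = [], [], []
        for seed, p in ((0, base), (1, scaled)):
            grid, vessels = default_scene(seed, (32, 32), 2)
            ds = generate_artificial_dataset(
                grid, vessels, params=p, noise=NoiseModel(DEFAULT_SIGMA), seed=seed
            )
            datas.append(ds.noisy)
            grids.append(grid)
            vessels_list.append(vessels)
        af = fit_images_jointly(datas, grids, vessels_list, n_starts=8, seed=0)
        est = af.estimate
        assert np.log10(est["scale_2"] / c2) == pytest.approx(0.0, abs=0.1)
        for name, truth in (("d_over_gamma", 64.0), ("rho", 2.0), ("s_s0", 100.0), ("bg", 40.0)):
            assert np.log10(est[name] / truth) == pytest.approx(0.0, abs=0.35)
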