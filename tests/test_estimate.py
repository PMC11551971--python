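"""Gradient-matching designs and regularized least-squares estimation."""

import numpy as np
import pytest
from scipy.interpolate import BSpline

from glvdriver import (
    SimulationConfig,
    build_difference_design,
    build_spline_design,
    estimate_model,
    fit_regularized,
    generate_dataset,
    relative_rmse,
)
from glvdriver.estimate import RegressionDesign
from glvdriver.preprocess import SmoothedTrajectory
from glvdriver.simulate import SubjectSeries, TimeSeriesDataset


def linear_eta_trajectory(subject, taxon, intercept, slope, t_min=0.0, t_max=10.0):
    """Trajectory with known eta(t) = intercept + slope * t (log scale)."""
    knots = np.array([t_min, t_min, t_max, t_max])
    coef = np.array([intercept, intercept + slope * (t_max - t_min)])
    return SmoothedTrajectory(
        subject=subject, taxon=taxon, spline=BSpline(knots, coef, 1),
        phi=1.0, t_min=t_min, t_max=t_max, lambda_=1.0, edf=2.0,
    )


class TestSplineDesign:
    def test_row_and_column_accounting(self):
        taxa = ["a", "b", "c"]
        times = np.arange(8, dtype=float)
        smoothed = {
            ("S1", t): linear_eta_trajectory("S1", t, 5.0, 0.01 * (i + 1))
            for i, t in enumerate(taxa)
        }
        design = build_spline_design(smoothed, {"S1": times[times <= 10]}, taxa)
        assert design.predictors.shape == (8, 3)
        assert design.responses.shape == (8, 3)

    def test_response_equals_eta_prime_for_known_curves(self):
        taxa = ["a", "b"]
        times = np.linspace(0, 10, 6)
        slopes = {"a": 0.05, "b": -0.08}
        smoothed = {
            ("S1", t): linear_eta_trajectory("S1", t, 6.0, slopes[t])
            for t in taxa
        }
        design = build_spline_design(smoothed, {"S1": times}, taxa)
        for k, t in enumerate(taxa):
            np.testing.assert_allclose(design.responses[:, k], slopes[t], rtol=1e-12)

    def test_missing_trajectory_named(self):
        smoothed = {("S1", "a"): linear_eta_trajectory("S1", "a", 5.0, 0.0)}
        with pytest.raises(ValueError, match="S1.*b"):
            build_spline_design(smoothed, {"S1": np.arange(5.0)}, ["a", "b"])


class TestDifferenceDesign:
    @staticmethod
    def dataset_from_counts(counts_per_subject, times_per_subject, taxa):
        subjects = [
            SubjectSeries(subject=f"S{i+1}", times=np.asarray(t, float),
                          counts=np.asarray(c))
            for i, (c, t) in enumerate(zip(counts_per_subject, times_per_subject))
        ]
        return TimeSeriesDataset(taxa=list(taxa), subjects=subjects)

    def test_constant_counts_give_zero_response(self):
        ds = self.dataset_from_counts(
            [np.full((5, 2), 7)], [np.arange(5)], ["a", "b"]
        )
        design = build_difference_design(ds)
        np.testing.assert_array_equal(design.responses, 0.0)

    def test_exponential_counts_recover_rate(self):
        t = np.arange(10, dtype=float)
        counts = np.round(100 * np.exp(0.1 * t)).astype(int)[:, None]
        ds = self.dataset_from_counts([counts], [t], ["a"])
        design = build_difference_design(ds)
        np.testing.assert_allclose(design.responses[:, 0], 0.1, atol=8e-3)

    def test_row_accounting_pooled_over_subjects(self):
        ds = generate_dataset(SimulationConfig(n=10, p=3, m=8, pi=0.5, phi=3.0, seed=2))
        design = build_difference_design(ds)
        assert design.predictors.shape == (70, 3)  # (m-1) * n rows

    def test_predictors_are_interval_means(self):
        counts = np.array([[10, 0], [30, 4]])
        ds = self.dataset_from_counts([counts], [[0.0, 2.0]], ["a", "b"])
        design = build_difference_design(ds)
        np.testing.assert_allclose(design.predictors[0], [20.0, 2.0])
        np.testing.assert_allclose(
            design.responses[0, 0], (np.log(31) - np.log(11)) / 2.0
        )


def exact_linear_design(seed=0, rows=40, p=4):
    """Design whose response is exactly alpha + X beta (no noise)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(10, 1000, size=(rows, p))
    alpha = rng.uniform(0, 0.2, p)
    beta = rng.normal(0, 1e-3, (p, p))
    Y = alpha + X @ beta.T
    groups = np.repeat(np.arange(rows // 5), 5)
    taxa = [f"t{i}" for i in range(p)]
    design = RegressionDesign(
        predictors=X, responses=Y, groups=groups, taxa=taxa
    )
    return design, alpha, beta


class TestFitRegularized:
    def test_lambda_zero_recovers_exact_system(self):
        design, alpha, beta = exact_linear_design()
        fit = fit_regularized(design, "ridge", lambda_grid=[0.0])
        np.testing.assert_allclose(fit.model.alpha, alpha, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(fit.model.beta, beta, rtol=1e-8, atol=1e-10)

    def test_lambda_zero_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        design, _, _ = exact_linear_design(seed=1)
        noisy = RegressionDesign(
            predictors=design.predictors,
            responses=design.responses + rng.normal(0, 0.05, design.responses.shape),
            groups=design.groups, taxa=design.taxa,
        )
        fit = fit_regularized(noisy, "ridge", lambda_grid=[0.0])
        ones = np.ones((noisy.predictors.shape[0], 1))
        A = np.hstack([ones, noisy.predictors])
        coef = np.linalg.solve(A.T @ A, A.T @ noisy.responses)
        np.testing.assert_allclose(fit.model.alpha, coef[0], rtol=1e-8)
        np.testing.assert_allclose(fit.model.beta, coef[1:].T, rtol=1e-8, atol=1e-12)

    def test_huge_ridge_penalty_shrinks_to_intercept(self):
        design, _, _ = exact_linear_design(seed=2)
        fit = fit_regularized(design, "ridge", lambda_grid=[1e9])
        assert np.abs(fit.model.beta).max() < 1e-8
        np.testing.assert_allclose(
            fit.model.alpha, design.responses.mean(axis=0), rtol=1e-4
        )

    def test_ridge_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(3)
        design, _, _ = exact_linear_design(seed=3)
        noisy = RegressionDesign(
            predictors=design.predictors,
            responses=design.responses + rng.normal(0, 0.05, design.responses.shape),
            groups=design.groups, taxa=design.taxa,
        )
        norms = []
        for lam in [0.0, 1e-2, 1.0, 1e2, 1e4, 1e6]:
            fit = fit_regularized(noisy, "ridge", lambda_grid=[lam])
            norms.append(np.linalg.norm(fit.model.beta))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_lasso_produces_more_exact_zeros_than_ridge(self):
        ds = generate_dataset(
            SimulationConfig(n=10, p=10, m=25, pi=0.8, phi=1.0, seed=4)
        )
        design = build_difference_design(ds)
        off = ~np.eye(10, dtype=bool)
        lasso = fit_regularized(design, "lasso")
        ridge = fit_regularized(design, "ridge")
        assert (lasso.model.beta[off] == 0).sum() > (ridge.model.beta[off] == 0).sum()

    def test_unknown_method_rejected(self):
        design, _, _ = exact_linear_design()
        with pytest.raises(ValueError):
            fit_regularized(design, "boosting")

    def test_constant_column_gets_zero_coefficient(self):
        design, _, _ = exact_linear_design(seed=5)
        X = design.predictors.copy()
        X[:, 2] = 42.0
        const_design = RegressionDesign(
            predictors=X, responses=design.responses,
            groups=design.groups, taxa=design.taxa,
        )
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_regularized(const_design, "ridge", lambda_grid=[1.0])
        assert np.all(fit.model.beta[:, 2] == 0)

    def test_fold_reduction_warns(self):
        design, _, _ = exact_linear_design(seed=6)
        two_group = RegressionDesign(
            predictors=design.predictors, responses=design.responses,
            groups=np.repeat([0, 1], design.predictors.shape[0] // 2),
            taxa=design.taxa,
        )
        with pytest.warns(UserWarning, match="folds"):
            fit_regularized(two_group, "ridge", cv_folds=5,
                            lambda_grid=[0.1, 1.0])


class TestEstimateModel:
    def test_deterministic(self, small_dataset):
        a = estimate_model(small_dataset, "spline", "ridge")
        b = estimate_model(small_dataset, "spline", "ridge")
        np.testing.assert_array_equal(a.model.alpha, b.model.alpha)
        np.testing.assert_array_equal(a.model.beta, b.model.beta)
        np.testing.assert_array_equal(a.lambdas, b.lambdas)

    def test_unknown_design_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            estimate_model(small_dataset, "fourier", "ridge")

    def test_low_noise_informative_recovery(self):
        # When initial states scatter around a feasible steady state the
        # transients actually sample the dynamics, and on long low-noise
        # series spline+ridge recovers a substantial part of the
        # interaction matrix — far better than the difference baseline.
        from glvdriver import add_nb_noise, draw_model, simulate_trajectory, steady_state
        from glvdriver.simulate import (
            SubjectSeries,
            TimeSeriesDataset,
            draw_sampling_design,
        )

        model = draw_model(5, 0.8, seed=2)  # has a feasible steady state
        ss = steady_state(model)
        assert ss.feasible
        rng = np.random.default_rng(0)
        grids = draw_sampling_design(10, 50, (1, 5), rng)
        subjects = []
        for i, t in enumerate(grids):
            f0 = ss.abundance * rng.uniform(0.3, 3.0, 5)
            latent = simulate_trajectory(model, f0, t)
            counts = add_nb_noise(latent, 1e4, rng)
            subjects.append(SubjectSeries(f"S{i+1}", t, counts, latent))
        ds = TimeSeriesDataset(list(model.taxa), subjects, model)

        spline_fit = estimate_model(ds, "spline", "ridge")
        diff_fit = estimate_model(ds, "difference", "ridge")
        spline_err = relative_rmse(spline_fit.model.beta, model.beta)
        diff_err = relative_rmse(diff_fit.model.beta, model.beta)
        assert spline_err < 0.7
        assert spline_err < diff_err
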