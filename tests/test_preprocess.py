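"""Table preparation and NB smoothing-spline denoising."""

import numpy as np
import pandas as pd
import pytest

from glvdriver import (
    add_nb_noise,
    evaluate_curve,
    evaluate_derivative,
    filter_prevalence,
    fit_nb_spline,
    select_top_abundant,
    to_absolute,
)
from glvdriver.preprocess import AbundanceTable


def make_table(values, taxa=None, subjects=None, times=None):
    taxa = taxa or [f"t{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(
        {
            "subject": subjects or ["X"] * len(samples),
            "time": times if times is not None else np.arange(len(samples), dtype=float),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return AbundanceTable(
        values=pd.DataFrame(values, index=taxa, columns=samples), meta=meta
    )


class TestToAbsolute:
    def test_scales_columns_by_biomass(self):
        rel = make_table(np.array([[0.5, 0.2], [0.5, 0.8]]))
        out = to_absolute(rel, {"s0": 1000.0, "s1": 10.0})
        np.testing.assert_allclose(out.values.to_numpy(), [[500, 2], [500, 8]])

    def test_elementwise_against_oracle(self):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(3), size=2).T
        rel = make_table(raw)
        biomass = {"s0": 1e4, "s1": 1e6}
        out = to_absolute(rel, biomass)
        expected = raw * np.array([1e4, 1e6])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_missing_biomass_names_sample(self):
        rel = make_table(np.array([[0.5], [0.5]]))
        with pytest.raises(ValueError, match="s0"):
            to_absolute(rel, {})


class TestFilterPrevalence:
    def test_boundary_is_strict(self):
        # present in 4 of 5 samples = 0.8, not > 0.8 -> dropped
        values = np.array([[1, 1, 1, 1, 0], [1, 1, 1, 1, 1]])
        out = filter_prevalence(make_table(values), threshold=0.8)
        assert out.taxa == ["t1"]

    def test_full_prevalence_always_kept(self):
        values = np.array([[2, 3, 4]])
        out = filter_prevalence(make_table(values), threshold=0.99)
        assert out.taxa == ["t0"]

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(1)
        values = (rng.random((10, 12)) < 0.6).astype(float)
        table = make_table(values)
        out = filter_prevalence(table, threshold=0.5)
        expected = [
            t for i, t in enumerate(table.taxa)
            if (values[i] > 0).mean() > 0.5
        ]
        assert out.taxa == expected

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            filter_prevalence(make_table(np.zeros((2, 3))), threshold=0.8)


class TestSelectTopAbundant:
    def test_identity_when_k_equals_taxa(self):
        table = make_table(np.arange(6.0).reshape(2, 3))
        assert select_top_abundant(table, k=2).taxa == table.taxa

    def test_tie_broken_by_label(self):
        values = np.array([[5.0, 5.0], [4.0, 6.0], [10.0, 20.0]])
        table = make_table(values, taxa=["b_tax", "a_tax", "big"])
        out = select_top_abundant(table, k=2)
        # b_tax and a_tax tie at 10; lexicographically first wins
        assert set(out.taxa) == {"big", "a_tax"}

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 10, size=(20, 30))
        table = make_table(values)
        out = select_top_abundant(table, k=10)
        sums = values.sum(axis=1)
        expected = set(np.array(table.taxa)[np.argsort(-sums)][:10])
        assert set(out.taxa) == expected

    def test_oversized_k_keeps_all_with_warning(self):
        table = make_table(np.ones((2, 2)))
        with pytest.warns(UserWarning):
            out = select_top_abundant(table, k=5)
        assert out.taxa == table.taxa


class TestNbSplineFit:
    def test_flat_series_recovered_with_small_derivative(self):
        # constant latent mean 500; fits over several noise draws stay near
        # the truth with a nearly flat derivative
        t = np.arange(1, 21, dtype=float)
        errs, derivs = [], []
        for seed in range(5):
            y = add_nb_noise(np.full(20, 500.0), 5.0, seed=seed)
            traj = fit_nb_spline(t, y, phi=5.0)
            f = traj.curve(t)
            errs.append(np.abs(f / 500.0 - 1).max())
            derivs.append(np.abs(traj.derivative(t)).max())
        assert np.mean(errs) < 0.10
        assert max(errs) < 0.15
        assert max(derivs) < 0.05 * 500

    def test_logistic_latent_recovery(self):
        # latent logistic curve; interior relative error below 10% averaged
        # over seeds at moderate noise
        t = np.linspace(0, 48, 25)
        latent = 20.0 * 200.0 / (1 + np.exp(-0.2 * (t - 15)))
        errs = []
        for seed in range(20):
            y = add_nb_noise(latent, 20.0, seed=seed)
            traj = fit_nb_spline(t, y, phi=20.0)
            interior = (t >= 5) & (t <= 43)
            rel = np.abs(traj.curve(t[interior]) / latent[interior] - 1)
            errs.append(rel.mean())
        assert np.mean(errs) < 0.10

    def test_exponential_growth_rate_recovery(self):
        # f = 100 e^{0.1 t}: the per-capita rate fhat'/fhat should sit near
        # 0.1 on the interior of the domain
        t = np.arange(0, 31, dtype=float)
        latent = 100.0 * np.exp(0.1 * t)
        means = []
        for seed in range(20):
            y = add_nb_noise(latent, 20.0, seed=seed)
            traj = fit_nb_spline(t, y, phi=20.0)
            interior = t[(t >= 5) & (t <= 25)]
            means.append(
                float(np.mean(traj.derivative(interior) / traj.curve(interior)))
            )
        assert abs(np.mean(means) - 0.1) < 0.02

    def test_all_zero_series_degenerate(self):
        traj = fit_nb_spline(np.arange(6.0), np.zeros(6), phi=1.0)
        assert traj.degenerate
        assert np.all(traj.derivative(np.arange(6.0)) == 0)
        assert np.all(traj.curve(np.arange(6.0)) > 0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_nb_spline([0.0, 1.0, 2.0], [1, 2, 3], phi=1.0)

    def test_positivity_everywhere(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 20, 12))
        y = rng.integers(0, 50, 12)
        traj = fit_nb_spline(t, y, phi=2.0)
        grid = np.linspace(t[0], t[-1], 200)
        assert np.all(traj.curve(grid) > 0)


class TestEvaluate:
    @pytest.fixture()
    def fitted(self):
        t = np.arange(0, 25, dtype=float)
        y = add_nb_noise(200 + 10 * t, 50.0, seed=0)
        return fit_nb_spline(t, y, phi=50.0), t

    def test_chain_rule_identity_exact(self, fitted):
        traj, t = fitted
        eta_prime = traj.spline.derivative()(t)
        np.testing.assert_array_equal(
            evaluate_derivative(traj, t), evaluate_curve(traj, t) * eta_prime
        )

    def test_derivative_matches_finite_difference(self, fitted):
        traj, t = fitted
        pts = np.linspace(1.0, 23.0, 7)
        h = 1e-5
        fd = (evaluate_curve(traj, pts + h) - evaluate_curve(traj, pts - h)) / (2 * h)
        np.testing.assert_allclose(evaluate_derivative(traj, pts), fd, rtol=1e-4)

    def test_extrapolation_refused(self, fitted):
        traj, _ = fitted
        with pytest.raises(ValueError):
            evaluate_curve(traj, 30.0)
        with pytest.raises(ValueError):
            evaluate_derivative(traj, -1.0)


class TestAbundanceTable:
    def test_rejects_duplicate_subject_time(self):
        values = pd.DataFrame(
            [[1.0, 2.0]], index=["t0"], columns=["s0", "s1"]
        )
        meta = pd.DataFrame(
            {"subject": ["X", "X"], "time": [1.0, 1.0]},
            index=pd.Index(["s0", "s1"], name="sample_id"),
        )
        with pytest.raises(ValueError):
            AbundanceTable(values=values, meta=meta)

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            make_table(np.array([[-1.0]]))
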