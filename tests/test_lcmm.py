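"""Mixture-of-LMM core: likelihood oracle, EM, fitting contracts."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from lcgrowth.basis import SplineSpec, broken_stick_basis
from lcgrowth.lcmm import (
    GrowthData,
    MixtureSpec,
    ParameterSet,
    _em_step,
    _Objective,
    class_mean_trajectories,
    fit,
    marginal_loglik,
    posterior_probabilities,
)

from conftest import make_two_class_panel


def tiny_instance(seed=0, n_subjects=3, K=2):
    """A tiny random-intercept instance with a dense brute-force oracle."""
    rng = np.random.default_rng(seed)
    ages = [0.0, 0.5, 1.0, 2.0]
    rows = []
    for i in range(n_subjects):
        for t in ages:
            rows.append((f"s{i}", "y", t, rng.normal()))
    zp = pd.DataFrame(rows, columns=["subject_id", "response", "age_years", "z"])
    data = GrowthData.from_panel(zp, ("y",))
    spec = MixtureSpec(
        responses=("y",), K=K, spline={"y": SplineSpec((0.25, 0.75))}, random_effects="intercept"
    )
    params = ParameterSet(
        xi=rng.normal(size=K - 1),
        beta={"y": rng.normal(size=(K, 4))},
        re_chol={"y": np.array([[0.6]])},
        sigma={"y": 0.5},
        omega=np.ones(K),
        link_params={"y": None},
    )
    return zp, data, spec, params, np.array(ages)


def brute_force(zp, spec, params, ages):
    """Dense-covariance evaluation of the mixture likelihood and posteriors."""
    X = broken_stick_basis(ages, spec.spline["y"])
    Z = np.ones((len(ages), 1))
    B = params.re_chol["y"] @ params.re_chol["y"].T
    Sigma = Z @ B @ Z.T + params.sigma["y"] ** 2 * np.eye(len(ages))
    pi = params.pi
    ll = 0.0
    posts = []
    for sid in sorted(zp.subject_id.unique()):
        y = zp[zp.subject_id == sid].sort_values("age_years").z.to_numpy()
        dens = np.array(
            [pi[g] * multivariate_normal.pdf(y, X @ params.beta["y"][g], Sigma) for g in range(spec.K)]
        )
        ll += np.log(dens.sum())
        posts.append(dens / dens.sum())
    return ll, np.array(posts)


class TestLikelihoodOracle:
    def test_marginal_loglik_matches_dense_brute_force(self):
        zp, data, spec, params, ages = tiny_instance()
        ll = marginal_loglik(params, data, spec)
        ll_bf, _ = brute_force(zp, spec, params, ages)
        assert abs(ll - ll_bf) < 1e-10

    def test_posteriors_match_brute_force_bayes_ratio(self):
        zp, data, spec, params, ages = tiny_instance(seed=3)
        post = posterior_probabilities(params, data, spec)
        _, post_bf = brute_force(zp, spec, params, ages)
        assert np.abs(post - post_bf).max() < 1e-10

    def test_label_permutation_invariance(self):
        zp, data, spec, params, ages = tiny_instance(seed=5, K=3)
        ll = marginal_loglik(params, data, spec)
        ll_perm = marginal_loglik(params.permuted([2, 0, 1]), data, spec)
        assert abs(ll - ll_perm) < 1e-10

    def test_single_class_posteriors_are_one(self):
        zp, data, spec, params, ages = tiny_instance(K=1)
        post = posterior_probabilities(params, data, spec)
        np.testing.assert_allclose(post, 1.0)

    def test_posterior_rows_normalized(self, two_class_fit):
        sums = two_class_fit.posteriors.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)


class TestEM:
    def test_em_never_decreases_loglik(self):
        panel = make_two_class_panel(n=60, sigma=0.4, seed=2)
        data = GrowthData.from_panel(panel, ("y",))
        spec = MixtureSpec(responses=("y",), K=2, spline={"y": SplineSpec((1.0, 2.5))})
        obj = _Objective(data, spec)
        rng = np.random.default_rng(0)
        params = ParameterSet(
            xi=np.zeros(1),
            beta={"y": rng.normal(scale=0.5, size=(2, 4))},
            re_chol={"y": np.array([[0.4, 0.0], [0.0, 0.1]])},
            sigma={"y": 0.6},
            omega=np.ones(2),
            link_params={"y": None},
        )
        lls = []
        for _ in range(40):
            params, ll = _em_step(params, obj)
            lls.append(ll)
        diffs = np.diff(lls)
        assert diffs.min() > -1e-8


class TestFitContracts:
    def test_noiseless_single_class_recovered_exactly(self):
        spec_knots = (1.0, 2.5)
        coef = np.array([0.5, -0.4, 0.3, 0.1])
        ages = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 5.0])
        X = broken_stick_basis(ages, SplineSpec(spec_knots))
        rows = []
        for i in range(30):
            for t, zv in zip(ages, X @ coef):
                rows.append((f"s{i}", "y", t, zv))
        zp = pd.DataFrame(rows, columns=["subject_id", "response", "age_years", "z"])
        data = GrowthData.from_panel(zp, ("y",))
        f = fit(data, MixtureSpec(responses=("y",), K=1, spline={"y": SplineSpec(spec_knots)}), seed=0)
        np.testing.assert_allclose(f.params.beta["y"][0], coef, atol=1e-4)
        assert f.params.sigma["y"] < 1e-2  # residual SD driven to its floor

    def test_well_separated_classes_classified_sharply(self, two_class_fit):
        # two classes six residual SDs apart: posteriors essentially 0/1
        assert two_class_fit.posteriors.max(axis=1).min() > 0.999

    def test_refit_is_bit_identical(self, two_class_panel):
        data = GrowthData.from_panel(two_class_panel, ("y",))
        spec = MixtureSpec(responses=("y",), K=2, spline={"y": SplineSpec((1.0, 2.5))})
        f1 = fit(data, spec, n_restarts=3, seed=0)
        f2 = fit(data, spec, n_restarts=3, seed=0)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(f1.posteriors, f2.posteriors)

    def test_loglik_nondecreasing_in_k(self, two_class_panel):
        data = GrowthData.from_panel(two_class_panel, ("y",))
        lls = []
        for K in (1, 2, 3):
            spec = MixtureSpec(responses=("y",), K=K, spline={"y": SplineSpec((1.0, 2.5))})
            lls.append(fit(data, spec, n_restarts=3, seed=0).loglik)
        assert lls[0] <= lls[1] + 1e-6
        assert lls[1] <= lls[2] + 1e-6

    def test_classes_sorted_by_descending_probability(self, two_class_fit):
        pi = two_class_fit.params.pi
        assert np.all(np.diff(pi) <= 1e-12)

    def test_allocation_is_argmax_of_posteriors(self, two_class_fit):
        np.testing.assert_array_equal(
            two_class_fit.allocation, np.argmax(two_class_fit.posteriors, axis=1)
        )

    def test_bivariate_single_class_sums_univariate_logliks(self):
        rng = np.random.default_rng(4)
        rows = []
        ages = [0.0, 1.0, 2.0, 4.0]
        for i in range(50):
            b = rng.normal(0, 0.3)
            for t in ages:
                rows.append((f"s{i}", "a", t, 0.2 - 0.1 * t + b + rng.normal(0, 0.2)))
                rows.append((f"s{i}", "b", t, -0.3 + 0.2 * t + b + rng.normal(0, 0.25)))
        zp = pd.DataFrame(rows, columns=["subject_id", "response", "age_years", "z"])
        sp = {"a": SplineSpec((1.5,)), "b": SplineSpec((1.5,))}
        lls = {}
        for resp in (("a",), ("b",), ("a", "b")):
            data = GrowthData.from_panel(zp, resp)
            spec = MixtureSpec(responses=resp, K=1, spline=sp)
            lls[resp] = fit(data, spec, seed=0).loglik
        assert lls[("a", "b")] == pytest.approx(lls[("a",)] + lls[("b",)], abs=1e-4)

    def test_fit_serialization_is_valid_json(self, two_class_fit, tmp_path):
        path = tmp_path / "fit.json"
        two_class_fit.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["spec"]["K"] == 2
        assert payload["loglik"] == two_class_fit.loglik
        assert len(payload["params"]["beta"]["y"]) == 2


class TestTrajectories:
    def test_single_class_curve_equals_basis_times_beta(self, two_class_panel):
        data = GrowthData.from_panel(two_class_panel, ("y",))
        spec = MixtureSpec(responses=("y",), K=1, spline={"y": SplineSpec((1.0, 2.5))})
        f = fit(data, spec, seed=0)
        grid = np.linspace(0, 5, 11)
        curves = class_mean_trajectories(f, grid)["y"]
        expected = broken_stick_basis(grid, SplineSpec((1.0, 2.5))) @ f.params.beta["y"][0]
        np.testing.assert_allclose(curves[0], expected)

    def test_curves_piecewise_linear_between_knots(self, two_class_fit):
        grid = np.linspace(1.2, 2.3, 12)  # strictly inside (1.0, 2.5)
        curves = class_mean_trajectories(two_class_fit, grid)["y"]
        second_diff = np.diff(curves, n=2, axis=1)
        assert np.abs(second_diff).max() < 1e-10


class TestLinks:
    def test_linear_link_matches_identity_family(self):
        # the linear link with unit latent residual SD reparametrizes the
        # identity model, so the maximized log-likelihoods agree
        panel = make_two_class_panel(n=60, sigma=0.3, seed=8)
        data = GrowthData.from_panel(panel, ("y",))
        sp = {"y": SplineSpec((1.0, 2.5))}
        f_id = fit(data, MixtureSpec(responses=("y",), K=2, spline=sp), n_restarts=3, seed=0)
        f_lin = fit(
            data,
            MixtureSpec(responses=("y",), K=2, spline=sp, link={"y": "linear"}),
            n_restarts=3,
            seed=0,
        )
        assert f_lin.loglik == pytest.approx(f_id.loglik, abs=0.05)

    def test_cubic_spline_link_fits_and_inverts(self):
        panel = make_two_class_panel(n=40, sigma=0.3, seed=9)
        data = GrowthData.from_panel(panel, ("y",))
        sp = {"y": SplineSpec((1.0, 2.5))}
        f = fit(
            data,
            MixtureSpec(responses=("y",), K=1, spline=sp, link={"y": "cubic_spline3"}),
            seed=0,
            em_max_iters=100,
        )
        assert np.isfinite(f.loglik)
        curves = class_mean_trajectories(f, np.linspace(0, 5, 11))["y"]
        assert np.all(np.isfinite(curves))
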