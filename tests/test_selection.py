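"""Fit statistics, class-number selection rule, stability matching."""

import numpy as np
import pandas as pd
import pytest

from lcgrowth.basis import SplineSpec
from lcgrowth.lcmm import GrowthData, MixtureFit, MixtureSpec, ParameterSet, fit
from lcgrowth.selection import (
    StabilityReport,
    fit_statistics,
    match_classes,
    recommend_from_table,
    stability_resample,
    sweep_k,
)

from conftest import make_two_class_panel


def _dummy_fit(K, loglik, n_params, posteriors):
    N = posteriors.shape[0]
    spec = MixtureSpec(responses=("y",), K=K, spline={"y": SplineSpec((1.0,))})
    params = ParameterSet(
        xi=np.zeros(K - 1),
        beta={"y": np.zeros((K, 3))},
        re_chol={"y": np.eye(2) * 0.1},
        sigma={"y": 0.5},
        omega=np.ones(K),
        link_params={"y": None},
    )
    return MixtureFit(
        spec=spec,
        params=params,
        loglik=loglik,
        n_params=n_params,
        posteriors=posteriors,
        allocation=np.argmax(posteriors, axis=1),
        subjects=np.arange(N),
        n_subjects=N,
        converged=True,
        n_restarts_used=1,
        seed=0,
    )


class TestFitStatistics:
    def test_bic_formula(self):
        post = np.ones((50, 1))
        st = fit_statistics(_dummy_fit(1, -100.0, 5, post))
        assert st.BIC == pytest.approx(200.0 + 5 * np.log(50))
        assert st.AIC == pytest.approx(210.0)

    def test_hard_posteriors_give_entropy_one_and_icl_equals_bic(self):
        post = np.zeros((40, 2))
        post[:20, 0] = 1.0
        post[20:, 1] = 1.0
        st = fit_statistics(_dummy_fit(2, -80.0, 7, post))
        assert st.relative_entropy == pytest.approx(1.0)
        assert st.ICL == pytest.approx(st.BIC)

    def test_uniform_posteriors_give_entropy_zero(self):
        post = np.full((30, 3), 1.0 / 3.0)
        st = fit_statistics(_dummy_fit(3, -80.0, 9, post))
        assert st.relative_entropy == pytest.approx(0.0, abs=1e-12)

    def test_icl_never_below_bic(self, two_class_fit):
        st = fit_statistics(two_class_fit)
        assert st.ICL >= st.BIC
        assert 0.0 <= st.relative_entropy <= 1.0

    def test_statistics_recomputable_from_serialized_fit(self, two_class_fit, tmp_path):
        # BIC/AIC/ICL are pure functions of loglik, n_params, N and the
        # posteriors, all of which survive serialization
        import json

        two_class_fit.to_json(tmp_path / "f.json")
        two_class_fit.posteriors_frame().to_csv(tmp_path / "p.csv", index=False)
        payload = json.loads((tmp_path / "f.json").read_text())
        post = pd.read_csv(tmp_path / "p.csv")[["class_1", "class_2"]].to_numpy()
        st = fit_statistics(two_class_fit)
        bic = -2 * payload["loglik"] + payload["n_params"] * np.log(payload["n_subjects"])
        ent = -(np.clip(post, 1e-300, 1) * np.log(np.clip(post, 1e-300, 1))).sum()
        assert bic == pytest.approx(st.BIC)
        assert bic + 2 * ent == pytest.approx(st.ICL, abs=1e-6)


class TestSelectionRule:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            rows,
            columns=["K", "BIC", "relative_entropy", "ICL", "min_class_fraction", "converged", "size_rule_ok"],
        )

    def test_small_class_excluded_regardless_of_bic(self):
        table = self._table(
            [
                (1, 500.0, 1.0, 500.0, 1.0, True, True),
                (2, 450.0, 0.9, 470.0, 0.4, True, True),
                (6, 300.0, 0.95, 320.0, 0.03, True, False),  # 3% class: ineligible
            ]
        )
        rec, notes = recommend_from_table(table)
        assert rec == 2

    def test_recommendation_withheld_when_no_k_qualifies(self):
        table = self._table([(2, 450.0, 0.9, 470.0, 0.02, True, False)])
        rec, notes = recommend_from_table(table)
        assert rec is None
        assert notes

    def test_criterion_conflicts_reported_not_resolved(self):
        table = self._table(
            [
                (2, 450.0, 0.5, 470.0, 0.4, True, True),
                (3, 460.0, 0.9, 465.0, 0.2, True, True),
            ]
        )
        rec, notes = recommend_from_table(table)
        assert rec == 2  # BIC rules
        assert any("disagree" in n for n in notes)

    def test_sweep_recovers_two_classes(self, two_class_panel):
        data = GrowthData.from_panel(two_class_panel, ("y",))
        base = MixtureSpec(responses=("y",), K=1, spline={"y": SplineSpec((1.0, 2.5))})
        res = sweep_k(data, base, k_min=1, k_max=3, n_restarts=3, seed=0)
        assert res.recommended_K == 2
        assert set(res.table["K"]) == {1, 2, 3}


class TestStability:
    def test_matching_is_symmetric(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(3, 20))
        b = rng.normal(size=(3, 20))
        _, r_ab = match_classes(a, b)
        _, r_ba = match_classes(b, a)
        assert r_ab == pytest.approx(r_ba)

    def test_identical_curves_match_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 10))
        perm, rmse = match_classes(a[[2, 0, 3, 1]], a)
        assert rmse == 0.0
        assert list(perm) != [0, 1, 2, 3]

    def test_full_sample_refits_self_match(self, two_class_panel, two_class_fit):
        data = GrowthData.from_panel(two_class_panel, ("y",))
        rep = stability_resample(
            data, two_class_fit.spec, two_class_fit, reps=2, frac=1.0, seed=0, n_restarts=2
        )
        assert max(rep.rmse) < 1e-4
        assert rep.pass_fraction == 1.0

    def test_nonconvergent_replicates_recorded_not_dropped(self, two_class_panel, two_class_fit):
        data = GrowthData.from_panel(two_class_panel, ("y",))
        # starve the optimizer so replicates cannot certify convergence
        rep = stability_resample(
            data,
            two_class_fit.spec,
            two_class_fit,
            reps=2,
            frac=0.5,
            seed=0,
            n_restarts=1,
            em_warm_iters=1,
            em_max_iters=2,
            refine=False,
        )
        assert len(rep.rmse) == 2
        assert rep.pass_fraction < 1.0
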