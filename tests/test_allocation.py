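"""Cross-tabulation, enrichment and abnormal-growth feature tables."""

import numpy as np
import pandas as pd
import pytest

from lcgrowth import published
from lcgrowth.allocation import (
    abnormal_flags,
    class_feature_table,
    crosstab,
    crosstab_from_counts,
    enrichment_flags,
    flag_ever,
    flag_rwg,
)


class TestCrossTab:
    def test_identical_labelings_are_diagonal(self):
        labels = pd.Series([1, 2, 1, 3, 2], index=list("abcde"))
        ct = crosstab(labels, labels)
        assert (np.diag(ct.counts) == [2, 2, 1]).all()
        assert np.diag(ct.row_pct).tolist() == [100.0, 100.0, 100.0]

    def test_published_row_percentages_reproduced(self):
        ct = crosstab_from_counts(published.multivariate_vs_height_counts())
        row_i = ct.row_pct.loc["i"]
        np.testing.assert_allclose(row_i, [3.14, 15.09, 68.55, 13.21], atol=0.005)
        assert ct.counts.loc["i"].sum() == 318

    def test_counts_transpose(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.integers(0, 3, 50), index=range(50))
        b = pd.Series(rng.integers(0, 4, 50), index=range(50))
        ct_ab = crosstab(a, b)
        ct_ba = crosstab(b, a)
        np.testing.assert_array_equal(ct_ab.counts.to_numpy(), ct_ba.counts.to_numpy().T)

    def test_row_percentages_sum_to_100(self):
        ct = crosstab_from_counts(published.multivariate_vs_weight_counts())
        np.testing.assert_allclose(ct.row_pct.sum(axis=1), 100.0, atol=0.1)

    def test_subject_mismatch_lists_offenders(self):
        a = pd.Series([1, 2], index=["x", "y"])
        b = pd.Series([1, 2], index=["x", "z"])
        with pytest.raises(ValueError, match="z"):
            crosstab(a, b)

    def test_uniform_random_labels_near_uniform_cells(self):
        rng = np.random.default_rng(42)
        n, R, C = 1000, 4, 4
        a = pd.Series(rng.integers(0, R, n), index=range(n))
        b = pd.Series(rng.integers(0, C, n), index=range(n))
        ct = crosstab(a, b)
        expected = n / (R * C)
        sd = np.sqrt(n * (1 / (R * C)) * (1 - 1 / (R * C)))
        assert np.abs(ct.counts.to_numpy() - expected).max() < 4 * sd


class TestEnrichment:
    def test_published_enriched_cell_flagged(self):
        ct = crosstab_from_counts(published.multivariate_vs_weight_counts())
        fl = enrichment_flags(ct)
        cell = fl[(fl.row == "iv") & (fl.col == "Gradual Increase; Gradual Decrease to Expected")].iloc[0]
        assert cell.flagged
        assert cell.row_pct == pytest.approx(89.5, abs=0.05)
        assert cell.col_marginal_pct == pytest.approx(51.1, abs=0.05)

    def test_exactly_uniform_table_has_no_flags(self):
        counts = pd.DataFrame(np.full((3, 4), 10))
        fl = enrichment_flags(crosstab_from_counts(counts))
        assert not fl.flagged.any()

    def test_single_column_never_flagged(self):
        counts = pd.DataFrame({"only": [5, 10, 20]})
        fl = enrichment_flags(crosstab_from_counts(counts))
        assert not fl.flagged.any()


def _series(pairs):
    return pd.DataFrame(pairs, columns=["age_years", "z"])


class TestRapidWeightGain:
    @pytest.mark.parametrize(
        "z_birth,z_9m,expected",
        [
            (-0.5, 0.2, True),    # gain 0.7
            (0.0, 0.67, True),    # boundary inclusive
            (0.0, 0.66, False),
        ],
    )
    def test_threshold(self, z_birth, z_9m, expected):
        d = _series([(0.0, z_birth), (0.75, z_9m)])
        assert flag_rwg(d) is expected

    def test_missing_anchor_is_undefined(self):
        assert flag_rwg(_series([(0.5, 0.0), (1.0, 1.0)])) is None  # no birth visit
        assert flag_rwg(_series([(0.0, 0.0), (2.0, 1.0)])) is None  # no 9-month visit

    def test_nearest_observation_in_window_used(self):
        d = _series([(0.0, 0.0), (0.62, 5.0), (0.74, 0.5), (0.9, 5.0)])
        assert flag_rwg(d) is False  # 0.74 is nearest to 0.75: gain 0.5


class TestEverFlags:
    def test_any_crossing_flags(self):
        assert flag_ever([-1.9, -2.1, -1.5], -2.0, "below") is True

    def test_exact_threshold_not_flagged(self):
        assert flag_ever([-2.0, -2.0], -2.0, "below") is False
        assert flag_ever([2.0], 2.0, "above") is False

    def test_empty_series_undefined(self):
        assert flag_ever([], -2.0, "below") is None


class TestFeatureTables:
    def test_published_rwg_percentage(self):
        # "Sharp Increase to High" zWeight class: 9 normal, 124 RWG -> 93.2%
        assert round(100 * 124 / 133, 1) == 93.2
        t = published.rwg_by_weight_class()
        pct = 100 * t.n_rwg / (t.n_rwg + t.n_normal)
        assert pct.iloc[3] == pytest.approx(93.2, abs=0.05)

    def test_published_stunting_percentage(self):
        t = published.stunted_by_height_class()
        row = t[t["class"] == "Sharp Decrease, Sharp Increase to Below Expected"].iloc[0]
        assert 100 * row.n_stunted / row.n_total == pytest.approx(73.0, abs=0.5)

    def test_class_feature_table_counts_and_percentages(self):
        labels = pd.Series(["a", "a", "b", "b", "b"], index=list("vwxyz"))
        flags = pd.DataFrame(
            {
                "subject_id": list("vwxyz"),
                "rwg": pd.array([True, False, True, True, None], dtype="boolean"),
            }
        )
        tab = class_feature_table(labels, flags, "rwg")
        a = tab[tab["class"] == "a"].iloc[0]
        b = tab[tab["class"] == "b"].iloc[0]
        coh = tab[tab["class"] == "Entire Cohort"].iloc[0]
        assert (a.n_flagged, a.n_total, a.percentage) == (1, 2, 50.0)
        assert (b.n_flagged, b.n_total) == (2, 2)  # undefined subject excluded
        assert coh.n_total == 4  # counts conservation over defined flags

    def test_all_false_flags_give_zero_percent(self):
        labels = pd.Series(["a", "b"], index=["u", "v"])
        flags = pd.DataFrame(
            {"subject_id": ["u", "v"], "rwg": pd.array([False, False], dtype="boolean")}
        )
        tab = class_feature_table(labels, flags, "rwg")
        assert (tab.percentage == 0.0).all()


class TestAbnormalFlagsFromPanel:
    def test_flags_derived_from_panel(self):
        rows = [
            ("s1", "zWeight", 0.0, -0.5), ("s1", "zWeight", 0.75, 0.3), ("s1", "zWeight", 3.0, 2.5),
            ("s1", "zHeight", 1.0, -2.5),
            ("s2", "zWeight", 0.0, 0.0), ("s2", "zWeight", 0.8, 0.1),
            ("s2", "zHeight", 1.0, -1.0),
        ]
        zp = pd.DataFrame(rows, columns=["subject_id", "response", "age_years", "z"])
        fl = abnormal_flags(zp).set_index("subject_id")
        assert fl.loc["s1", "rwg"] == True  # noqa: E712 - nullable boolean
        assert fl.loc["s1", "ever_overweight"] == True  # noqa: E712
        assert fl.loc["s1", "ever_stunted"] == True  # noqa: E712
        assert fl.loc["s2", "rwg"] == False  # noqa: E712
        assert fl.loc["s2", "ever_underweight"] == False  # noqa: E712
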