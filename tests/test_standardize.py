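"""Standardization: LMS transforms, replicate rules, reference switching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lcgrowth as lg
from lcgrowth.lms import ChartRangeError, InvalidMeasurementError
from lcgrowth.standardize import (
    WEEKS_PER_YEAR,
    AnthroRecord,
    UnresolvedReplicateError,
    reference_lookup,
    resolve_replicates,
    standardize_cohort,
)


class TestLMSTransform:
    def test_median_maps_to_zero(self):
        assert lg.lms_zscore(10.0, 0.7, 10.0, 0.12) == pytest.approx(0.0)

    def test_linear_case(self):
        assert lg.lms_zscore(11.0, 1.0, 10.0, 0.1) == pytest.approx(1.0)

    def test_continuous_in_box_cox_power_at_zero(self):
        near = lg.lms_zscore(11.0, 1e-8, 10.0, 0.1)
        at = lg.lms_zscore(11.0, 0.0, 10.0, 0.1)
        assert abs(near - at) < 1e-6

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            lg.lms_zscore(-1.0, 1.0, 10.0, 0.1)
        with pytest.raises(InvalidMeasurementError):
            lg.lms_zscore(1.0, 1.0, 10.0, -0.1)

    def test_inverse_trivial_cases(self):
        assert lg.lms_inverse(0.0, 0.5, 10.0, 0.1) == pytest.approx(10.0)
        assert lg.lms_inverse(1.0, 1.0, 10.0, 0.1) == pytest.approx(11.0)

    def test_round_trip_on_random_parameters(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            L = rng.uniform(-2.0, 2.0)
            if rng.random() < 0.1:
                L = 0.0
            M = rng.uniform(0.5, 120.0)
            S = rng.uniform(0.01, 0.3)
            z = rng.uniform(-4.0, 4.0)
            if L != 0.0 and 1.0 + L * S * z <= 1e-3:
                continue
            x = lg.lms_inverse(z, L, M, S)
            worst = max(worst, abs(lg.lms_zscore(x, L, M, S) - z))
        assert worst < 1e-9

    @given(
        z=st.floats(-3, 3),
        L=st.floats(-1.5, 1.5),
        M=st.floats(0.5, 100),
        S=st.floats(0.02, 0.2),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_property(self, z, L, M, S):
        if L != 0.0 and 1.0 + L * S * z <= 1e-3:
            return
        x = lg.lms_inverse(z, L, M, S)
        assert lg.lms_zscore(x, L, M, S) == pytest.approx(z, abs=1e-9)


class TestReplicateResolution:
    @pytest.mark.parametrize(
        "reps,tol,expected",
        [
            ((50.0, 50.4), 0.5, 50.0),        # agree: first measurement used
            ((50.0, 50.6, 50.3), 0.5, 50.3),  # disagree: third measurement used
            ((2.50, 2.60), 0.1, 2.50),        # boundary inclusive: |diff| == tol
        ],
    )
    def test_resolution_rules(self, reps, tol, expected):
        assert resolve_replicates(reps, tol) == pytest.approx(expected)

    def test_unresolved_pair_raises(self):
        with pytest.raises(UnresolvedReplicateError):
            resolve_replicates((50.0, 50.6), 0.5)


class TestReferenceLookup:
    def test_preterm_uses_fenton_before_50_weeks_pma(self):
        age = 10.0 / WEEKS_PER_YEAR
        role, lookup = reference_lookup(32.0, age)
        assert role == "Fenton"
        assert lookup * WEEKS_PER_YEAR == pytest.approx(42.0)

    def test_term_child_uses_who_at_chronological_age(self):
        assert reference_lookup(40.0, 1.0) == ("WHO", 1.0)

    def test_preterm_corrected_age_on_who(self):
        role, lookup = reference_lookup(32.0, 1.0)
        assert role == "WHO"
        assert lookup == pytest.approx(1.0 - 8.0 * 7.0 / 365.25, abs=1e-9)

    def test_correction_stops_at_two_years(self):
        assert reference_lookup(32.0, 2.0) == ("WHO", 2.0)

    def test_corrected_age_at_handover(self):
        # at the 50-week handover, corrected age is pma - 40 weeks
        ga = 28.0
        age = (50.0 - ga) / WEEKS_PER_YEAR
        role, lookup = reference_lookup(ga, age)
        assert role == "WHO"
        assert lookup == pytest.approx(10.0 / WEEKS_PER_YEAR)

    def test_composite_lookup_age_floored_at_zero(self):
        from lcgrowth.standardize import _who_age

        # a very preterm newborn: chronological age minus the term deficit
        # would be negative; the composite responses use age floored at 0
        assert _who_age(28.0, 0.05) == 0.0
        assert _who_age(40.0, 0.05) == 0.05

    def test_handover_happens_exactly_at_pma_50(self):
        ga = 30.0
        eps = 1e-9
        before = (50.0 - ga) / WEEKS_PER_YEAR - eps
        after = (50.0 - ga) / WEEKS_PER_YEAR + eps
        assert reference_lookup(ga, before)[0] == "Fenton"
        assert reference_lookup(ga, after)[0] == "WHO"

    def test_term_anchor_means_no_correction_for_ga_40(self):
        # a (hypothetical) ga=40 child would have identical corrected and
        # chronological ages; the formula is continuous in ga at term
        corrected = 1.0 - (40.0 - 40.0) / WEEKS_PER_YEAR
        assert corrected == 1.0


class TestStandardizeCohort:
    def test_bmi_arithmetic(self):
        assert 3.2 / (50.0 / 100.0) ** 2 == pytest.approx(12.8)

    def test_median_child_maps_to_zero_everywhere(self, charts):
        chart_h = charts.get("height_for_age", "TOY")
        chart_w = charts.get("weight_for_age", "TOY")
        records = []
        for age in (0.0, 0.5, 1.0, 3.0, 5.0):
            h = chart_h.inverse(0.0, "female", age)
            w = chart_w.inverse(0.0, "female", age)
            records.append(
                AnthroRecord("kid", "female", 40.0, age, (h, h), (w, w))
            )
        zpanel, excl = standardize_cohort(records, charts)
        hz = zpanel[zpanel.response.isin(["zHeight", "zWeight"])]["z"]
        assert np.abs(hz).max() < 1e-9

    def test_round_trip_recovers_generating_z(self, charts):
        spec = lg.dchs_like(n_subjects=40, seed=5)
        spec.replicate_sd = {"height": 0.0, "weight": 0.0}
        spec.third_replicate_prob = 0.0
        cohort = lg.simulate_raw(spec, charts)
        zpanel, _ = standardize_cohort(cohort.raw_panel, charts, z_limit=np.inf)
        gen = cohort.zpanel.set_index(["subject_id", "response", "age_years"])["z"]
        got = zpanel[zpanel.response.isin(["zHeight", "zWeight"])].set_index(
            ["subject_id", "response", "age_years"]
        )["z"]
        joined = pd.concat([gen, got], axis=1, keys=["gen", "got"]).dropna()
        assert len(joined) == len(gen)
        assert (joined.gen - joined.got).abs().max() < 1e-6

    def test_no_silent_drops(self, charts):
        spec = lg.dchs_like(n_subjects=30, seed=9)
        cohort = lg.simulate_raw(spec, charts)
        zpanel, excl = standardize_cohort(cohort.raw_panel, charts)
        n_visits = len(cohort.raw_panel)
        assert len(zpanel) + len(excl) == n_visits * 4

    def test_out_of_range_lookup_is_excluded_not_fatal(self, charts):
        rec = AnthroRecord("x", "male", 40.0, 1.0, (500.0, 500.0), (3.0, 3.0))
        zpanel, excl = standardize_cohort([rec], charts)
        assert "chart_range" in set(excl["reason"]) or "z_filter" in set(excl["reason"])

    def test_implausible_z_filtered(self, charts):
        chart_w = charts.get("weight_for_age", "TOY")
        w_bad = chart_w.inverse(6.5, "male", 1.0)
        rec = AnthroRecord("x", "male", 40.0, 1.0, (75.0, 75.0), (w_bad, w_bad))
        zpanel, excl = standardize_cohort([rec], charts, z_limit=6.0)
        assert (excl["reason"] == "z_filter").any()
        assert "zWeight" not in set(zpanel["response"])

    def test_chart_range_error_message(self, charts):
        with pytest.raises(ChartRangeError):
            charts.get("height_for_age", "TOY").lms_at("male", 9.9)
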