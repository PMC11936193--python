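"""Standardize raw child anthropometry to z-scores with reference switching.

Implements the measurement protocol of a birth cohort in which height
and weight are taken twice per visit (a third time when the first two
disagree), and z-scores are computed against a preterm (Fenton-role)
reference up to 50 weeks postmenstrual age and an at-term (WHO-role)
reference thereafter, with gestational-age-corrected lookup ages for
preterm children until age 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lcgrowth.lms import ChartRangeError, ChartSet, InvalidMeasurementError

WEEKS_PER_YEAR = 365.25 / 7.0
TERM_GA_WEEKS = 40.0           # term anchor used for gestational-age correction
PRETERM_BELOW_WEEKS = 37.0     # preterm = born before 37 completed weeks
FENTON_PMA_LIMIT_WEEKS = 50.0  # preterm reference used while pma < 50 weeks
GA_CORRECTION_UNTIL_YEARS = 2.0

HEIGHT_TOLERANCE_CM = 0.5
WEIGHT_TOLERANCE_KG = 0.1

RESPONSES = ("zHeight", "zWeight", "zBMI", "zWFH")

PANEL_COLUMNS = [
    "subject_id", "sex", "ga_weeks", "age_years",
    "height1", "height2", "height3", "weight1", "weight2", "weight3",
]
ZPANEL_COLUMNS = ["subject_id", "response", "age_years", "z", "chart_used", "corrected_age_years"]


class UnresolvedReplicateError(ValueError):
    """First two replicates disagree beyond tolerance and no third was taken."""


@dataclass
class AnthroRecord:
    """Raw duplicated measurements from one visit, with subject metadata."""

    subject_id: object
    sex: str
    ga_weeks: float
    age_years: float
    height_reps: tuple  # 2-3 values, cm
    weight_reps: tuple  # 2-3 values, kg

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 20.0 <= self.ga_weeks <= 44.0:
            raise ValueError(f"ga_weeks outside [20, 44]: {self.ga_weeks}")
        if not 0.0 <= self.age_years <= 5.5:
            raise ValueError(f"age_years outside [0, 5.5]: {self.age_years}")
        for name, reps in (("height", self.height_reps), ("weight", self.weight_reps)):
            if not 2 <= len(reps) <= 3:
                raise ValueError(f"{name}_reps needs 2-3 replicates, got {len(reps)}")
            if any(r <= 0 for r in reps):
                raise ValueError(f"nonpositive {name} replicate")


def resolve_replicates(reps, tolerance: float) -> float:
    """Resolve duplicated technical measurements into one accepted value.

    The first value is used when the first two agree within ``tolerance``
    (inclusive); otherwise the third measurement is used.
    """
    reps = [float(r) for r in reps]
    # inclusive boundary, robust to binary representation of decimal inputs
    if abs(reps[0] - reps[1]) <= tolerance * (1.0 + 1e-9) + 1e-12:
        return reps[0]
    if len(reps) < 3:
        raise UnresolvedReplicateError(
            f"replicates {reps[0]} and {reps[1]} differ by more than {tolerance} and no third value exists"
        )
    return reps[2]


def reference_lookup(ga_weeks: float, age_years: float) -> tuple[str, float]:
    """Which reference role applies at this visit, and at what lookup age.

    Term children (ga >= 37 weeks) always use the at-term (WHO-role)
    reference at chronological age.  Preterm children use the
    preterm (Fenton-role) reference, indexed by postmenstrual age,
    while pma < 50 weeks; afterwards the WHO-role reference with a
    gestational-age-corrected age (chronological age minus the deficit
    to a 40-week term anchor, floored at zero) until age 2, and
    chronological age from age 2 onwards.

    Returns ``(role, lookup_age_years)`` with role 'WHO' or 'Fenton';
    Fenton lookup ages are postmenstrual age expressed in years.
    """
    if ga_weeks >= PRETERM_BELOW_WEEKS:
        return "WHO", age_years
    pma_weeks = ga_weeks + age_years * WEEKS_PER_YEAR
    if pma_weeks < FENTON_PMA_LIMIT_WEEKS:
        return "Fenton", pma_weeks / WEEKS_PER_YEAR
    if age_years < GA_CORRECTION_UNTIL_YEARS:
        corrected = age_years - (TERM_GA_WEEKS - ga_weeks) / WEEKS_PER_YEAR
        return "WHO", max(corrected, 0.0)
    return "WHO", age_years


def _who_age(ga_weeks: float, age_years: float) -> float:
    """Gestational-age-corrected lookup age on the at-term reference.

    Same correction convention as :func:`reference_lookup` but always
    on the WHO-role chart, used for the composite responses (zBMI,
    zWFH) which the protocol standardizes against WHO references only.
    """
    if ga_weeks >= PRETERM_BELOW_WEEKS or age_years >= GA_CORRECTION_UNTIL_YEARS:
        return age_years
    return max(age_years - (TERM_GA_WEEKS - ga_weeks) / WEEKS_PER_YEAR, 0.0)


def _resolve_source(charts: ChartSet, role: str) -> str:
    """Map a reference role onto a chart source present in the set."""
    if role == "Fenton":
        return "Fenton"
    if ("height_for_age", "WHO") in charts:
        return "WHO"
    return "TOY"


def standardize_cohort(
    panel,
    charts: ChartSet,
    z_limit: float = 6.0,
):
    """Standardize a raw long-format panel into a z-score panel.

    Parameters
    ----------
    panel
        DataFrame in the raw-panel schema (``PANEL_COLUMNS``) or an
        iterable of :class:`AnthroRecord`.
    charts
        Reference charts covering the required measures/sources.
    z_limit
        Plausibility filter: observations with ``|z| > z_limit`` are
        treated as instrumental/measurement error and excluded
        (WHO-convention default 6).

    Returns
    -------
    (zpanel, exclusions)
        ``zpanel`` in the ZPanel schema (one row per visit x response);
        ``exclusions`` logs every dropped observation with its reason,
        so that emitted + excluded = visits x responses.
    """
    records = _coerce_records(panel)
    rows: list[tuple] = []
    excluded: list[tuple] = []

    def drop(rec, response, reason):
        excluded.append((rec.subject_id, response, rec.age_years, reason))

    for rec in records:
        try:
            height = resolve_replicates(rec.height_reps, HEIGHT_TOLERANCE_CM)
        except UnresolvedReplicateError:
            height = None
        try:
            weight = resolve_replicates(rec.weight_reps, WEIGHT_TOLERANCE_KG)
        except UnresolvedReplicateError:
            weight = None

        role, lookup_age = reference_lookup(rec.ga_weeks, rec.age_years)
        source = _resolve_source(charts, role)
        who_source = _resolve_source(charts, "WHO")
        who_age = _who_age(rec.ga_weeks, rec.age_years)

        # (response, measure, source, axis value, raw value, corrected age)
        plan = []
        if height is None:
            drop(rec, "zHeight", "unresolved_replicates")
        else:
            plan.append(("zHeight", "height_for_age", source, lookup_age, height, lookup_age))
        if weight is None:
            drop(rec, "zWeight", "unresolved_replicates")
        else:
            plan.append(("zWeight", "weight_for_age", source, lookup_age, weight, lookup_age))
        if height is None or weight is None:
            drop(rec, "zBMI", "unresolved_replicates")
            drop(rec, "zWFH", "unresolved_replicates")
        else:
            bmi = weight / (height / 100.0) ** 2
            plan.append(("zBMI", "bmi_for_age", who_source, who_age, bmi, who_age))
            plan.append(("zWFH", "weight_for_length", who_source, height, weight, who_age))

        for response, measure, src, axis_value, value, corrected in plan:
            try:
                z = charts.get(measure, src).zscore(value, rec.sex, axis_value)
            except ChartRangeError:
                drop(rec, response, "chart_range")
                continue
            except InvalidMeasurementError:
                drop(rec, response, "invalid_measurement")
                continue
            if not np.isfinite(z) or abs(z) > z_limit:
                drop(rec, response, "z_filter")
                continue
            rows.append((rec.subject_id, response, rec.age_years, z, src, corrected))

    zpanel = pd.DataFrame(rows, columns=ZPANEL_COLUMNS)
    exclusions = pd.DataFrame(excluded, columns=["subject_id", "response", "age_years", "reason"])
    return zpanel, exclusions


def _coerce_records(panel):
    if isinstance(panel, pd.DataFrame):
        return list(records_from_panel(panel))
    return list(panel)


def records_from_panel(panel: pd.DataFrame):
    """Yield :class:`AnthroRecord` from a raw-panel DataFrame (blank third replicate allowed)."""
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    for row in panel.itertuples(index=False):
        h = [row.height1, row.height2, row.height3]
        w = [row.weight1, row.weight2, row.weight3]
        yield AnthroRecord(
            subject_id=row.subject_id,
            sex=row.sex,
            ga_weeks=float(row.ga_weeks),
            age_years=float(row.age_years),
            height_reps=tuple(float(v) for v in h if pd.notna(v)),
            weight_reps=tuple(float(v) for v in w if pd.notna(v)),
        )


def read_panel_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_zpanel_csv(zpanel: pd.DataFrame, path) -> None:
    zpanel[ZPANEL_COLUMNS].to_csv(path, index=False)
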