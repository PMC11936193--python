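"""Synthetic birth-cohort generator with known latent growth classes.

Emulates the statistical structure assumed by the trajectory
analysis: each child belongs to a latent class drawn from fixed
proportions; its z-score trajectory per response is a class-specific
broken-stick mean curve plus a subject-level random intercept/slope
and residual noise; visits follow the cohort schedule (birth, 6, 10,
14 weeks, 6, 9, 12 months, then 6-monthly to 5 years); loss to
follow-up is monotone (once gone, gone) and weighted toward infancy;
a configurable fraction of children is preterm with a late-preterm
gestational-age mode.  A raw-measurement layer inverts the generating
z-scores through a smooth synthetic ("toy") reference chart and adds
duplicated technical replicates, so the standardization stage can be
exercised end to end.  All randomness flows from one seed through
``numpy.random.default_rng`` (PCG64), so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lcgrowth.basis import SplineSpec, broken_stick_basis
from lcgrowth.lms import CHART_COLUMNS, ChartSet, lms_inverse
from lcgrowth.standardize import (
    HEIGHT_TOLERANCE_CM,
    PANEL_COLUMNS,
    WEEKS_PER_YEAR,
    WEIGHT_TOLERANCE_KG,
    ZPANEL_COLUMNS,
    reference_lookup,
)

#: Cohort visit schedule in years: birth, 6/10/14 weeks, 6/9/12 months,
#: then 6-monthly until 5 years (15 visits).
DEFAULT_SCHEDULE = (
    0.0, 6 / 52.18, 10 / 52.18, 14 / 52.18,
    0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0,
)


@dataclass
class SimSpec:
    """Generating parameters for a synthetic cohort.

    ``class_coef`` maps response -> (K, p) broken-stick coefficient
    rows on the knots in ``knots`` (truncated-power basis with
    intercept).  Random effects are subject-level intercept and age
    slope with SDs ``re_sd`` and correlation ``re_corr``, shared
    across classes.  ``ltfu_fraction`` children drop out permanently
    at a random visit weighted toward infancy; ``preterm_fraction``
    are born before 37 weeks with a late-preterm mode.
    """

    n_subjects: int
    class_proportions: tuple
    knots: dict                      # response -> knot tuple
    class_coef: dict                 # response -> (K, p) array-like
    re_sd: tuple = (0.5, 0.1)        # (intercept, slope) SD in z-units
    re_corr: float = -0.2
    sigma: dict = None               # response -> residual SD (default 0.3)
    schedule: tuple = DEFAULT_SCHEDULE
    ltfu_fraction: float = 0.122
    preterm_fraction: float = 0.167
    replicate_sd: dict = None        # measure -> SD (default height 0.15 cm, weight 0.03 kg)
    third_replicate_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.class_proportions, dtype=float)
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("class proportions must be positive and sum to 1")
        sched = tuple(float(t) for t in self.schedule)
        if sched[0] != 0.0 or not all(a < b for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule must start at 0 and be strictly increasing")
        self.schedule = sched
        self.sigma = dict(self.sigma or {})
        self.class_coef = {r: np.asarray(c, dtype=float) for r, c in self.class_coef.items()}
        for r, coef in self.class_coef.items():
            self.sigma.setdefault(r, 0.3)
            if coef.shape != (len(pi), len(self.knots[r]) + 2):
                raise ValueError(f"class_coef[{r!r}] must be (K, n_knots + 2)")
            if self.sigma[r] < 0:
                raise ValueError("sigma must be >= 0")
        if self.replicate_sd is None:
            self.replicate_sd = {"height": 0.15, "weight": 0.03}
        if any(s < 0 for s in self.re_sd) or any(s < 0 for s in self.replicate_sd.values()):
            raise ValueError("SDs must be >= 0")

    @property
    def K(self) -> int:
        return len(self.class_proportions)

    @property
    def responses(self) -> tuple:
        return tuple(self.class_coef)


@dataclass
class SimulatedCohort:
    """A generated cohort: true labels, z layer, optional raw layer."""

    spec: SimSpec
    true_labels: pd.Series          # class index per subject id (0-based)
    zpanel: pd.DataFrame            # generating z values, ZPanel schema
    ga_weeks: pd.Series             # gestational age per subject
    sex: pd.Series
    raw_panel: pd.DataFrame = field(default=None)  # raw schema, when simulated


def _mean_curve(spec: SimSpec, response: str, g: int, ages: np.ndarray) -> np.ndarray:
    basis = broken_stick_basis(ages, SplineSpec(spec.knots[response]))
    return basis @ spec.class_coef[response][g]


def _draw_ga(rng: np.random.Generator, n: int, preterm_fraction: float) -> np.ndarray:
    """Gestational ages: term mass at 37-42 weeks, late-preterm-mode tail 28-37."""
    preterm = rng.random(n) < preterm_fraction
    ga = np.empty(n)
    n_pre = int(preterm.sum())
    # late-preterm mode: triangular peaking just below 37 weeks
    ga[preterm] = rng.triangular(28.0, 36.0, 36.99, size=n_pre)
    ga[~preterm] = rng.uniform(37.0, 42.0, size=n - n_pre)
    return np.round(ga * 2) / 2  # half-week resolution


def _dropout_visit(rng, n, schedule, ltfu_fraction):
    """Visit index after which each subject is lost (len(schedule) = never).

    Dropout is completely at random across subjects; among the lost,
    the dropout visit is weighted toward infancy (most loss before
    6 months), and monotone: once gone, gone.
    """
    n_vis = len(schedule)
    lost = rng.random(n) < ltfu_fraction
    cut = np.full(n, n_vis)
    t = np.asarray(schedule[1:])
    weights = np.exp(-2.0 * t)
    weights /= weights.sum()
    cut[lost] = 1 + rng.choice(len(t), size=int(lost.sum()), p=weights)
    return cut


def simulate_zpanel(spec: SimSpec) -> SimulatedCohort:
    """Generate the z-score layer of a synthetic cohort.

    z_ij = basis(t_ij) . beta_class + b0_i + b1_i t_ij + eps_ij, with
    class labels Categorical(pi), bivariate-normal random effects and
    N(0, sigma^2) residual noise; monotone dropout thins the schedule.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    subjects = np.array([f"S{i:05d}" for i in range(n)])
    labels = rng.choice(spec.K, size=n, p=np.asarray(spec.class_proportions))
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    ga = _draw_ga(rng, n, spec.preterm_fraction)
    cut = _dropout_visit(rng, n, spec.schedule, spec.ltfu_fraction)

    s0, s1 = spec.re_sd
    # explicit 2x2 Cholesky factor: exact for degenerate (zero-SD) cases
    L = np.array([[s0, 0.0], [spec.re_corr * s1, s1 * np.sqrt(max(1.0 - spec.re_corr**2, 0.0))]])
    b = rng.standard_normal((n, 2)) @ L.T

    sched = np.asarray(spec.schedule)
    rows = []
    for i in range(n):
        ages = sched[: cut[i]]
        re_part = b[i, 0] + b[i, 1] * ages
        for r in spec.responses:
            eps = rng.normal(0.0, spec.sigma[r], size=len(ages))
            z = _mean_curve(spec, r, labels[i], ages) + re_part + eps
            for t, zv in zip(ages, z):
                rows.append((subjects[i], r, float(t), float(zv), "TOY", float(t)))
    zpanel = pd.DataFrame(rows, columns=ZPANEL_COLUMNS)
    return SimulatedCohort(
        spec=spec,
        true_labels=pd.Series(labels, index=subjects, name="true_class"),
        zpanel=zpanel,
        ga_weeks=pd.Series(ga, index=subjects, name="ga_weeks"),
        sex=pd.Series(sex, index=subjects, name="sex"),
    )


def simulate_raw(spec: SimSpec, charts: ChartSet) -> SimulatedCohort:
    """Generate raw duplicated measurements by inverting the z layer.

    Requires zHeight and zWeight in the spec.  Each generating z is
    mapped to a raw measurement through the chart the standardization
    stage will itself select (same reference-switching rules), then
    jittered with replicate noise; with ``third_replicate_prob`` the
    first two replicates are pushed beyond the acceptance tolerance
    and a third, in-tolerance replicate is emitted.
    """
    if not {"zHeight", "zWeight"} <= set(spec.responses):
        raise ValueError("raw layer requires zHeight and zWeight in the spec")
    cohort = simulate_zpanel(spec)
    rng = np.random.default_rng(spec.seed + 1)
    z = cohort.zpanel.pivot_table(
        index=["subject_id", "age_years"], columns="response", values="z"
    ).reset_index()

    measures = {"zHeight": ("height_for_age", "height"), "zWeight": ("weight_for_age", "weight")}
    tol = {"height": HEIGHT_TOLERANCE_CM, "weight": WEIGHT_TOLERANCE_KG}
    rows = []
    for row in z.itertuples(index=False):
        sid = row.subject_id
        ga = float(cohort.ga_weeks[sid])
        sex = cohort.sex[sid]
        age = float(row.age_years)
        role, lookup_age = reference_lookup(ga, age)
        source = "Fenton" if role == "Fenton" else ("WHO" if ("height_for_age", "WHO") in charts else "TOY")
        reps: dict[str, tuple] = {}
        for resp, (measure, kind) in measures.items():
            chart = charts.get(measure, source)
            x = chart.inverse(getattr(row, resp), sex, lookup_age)
            sd = spec.replicate_sd[kind]
            if rng.random() < spec.third_replicate_prob:
                # deliberately discordant first pair, as when a measurement slips
                split = 0.75 * tol[kind]
                reps[kind] = (x - split, x + split, x + rng.normal(0.0, sd))
            else:
                r1, r2 = x + rng.normal(0.0, sd, size=2)
                if abs(r1 - r2) > tol[kind]:
                    # protocol: a third measurement is taken whenever the
                    # first two disagree beyond tolerance
                    reps[kind] = (r1, r2, x + rng.normal(0.0, sd))
                else:
                    reps[kind] = (r1, r2, np.nan)
        rows.append(
            (sid, sex, ga, age, *reps["height"], *reps["weight"])
        )
    raw = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    cohort.raw_panel = raw
    return cohort


# ---------------------------------------------------------------------------
# Toy reference charts
# ---------------------------------------------------------------------------


def toy_reference(
    height_birth_cm: float = 50.0,
    height_adult_cm: float = 112.0,
    height_rate: float = 0.55,
    weight_birth_kg: float = 3.3,
    weight_plateau_kg: float = 19.0,
    weight_rate: float = 0.50,
    n_grid: int = 120,
) -> ChartSet:
    """Smooth synthetic reference charts for all four measures.

    All values are synthetic stand-ins with plausible shapes (saturating
    median growth curves, constant Box-Cox power and coefficient of
    variation), not official reference values.  Term-role charts carry
    source 'TOY' on an age axis covering [0, 5.5] years; the
    preterm-role charts carry source 'Fenton' on a postmenstrual-age
    axis covering 20-52 weeks.  Sexes differ by a small median offset.
    """

    def m_height(age, male):
        return (height_adult_cm + (1.0 if male else 0.0)) - (
            height_adult_cm + (1.0 if male else 0.0) - height_birth_cm
        ) * np.exp(-height_rate * age)

    def m_weight(age, male):
        return (weight_plateau_kg + (0.4 if male else 0.0)) - (
            weight_plateau_kg + (0.4 if male else 0.0) - weight_birth_kg
        ) * np.exp(-weight_rate * age)

    ages = np.linspace(0.0, 5.5, n_grid)
    rows = []
    for sex, male in (("female", False), ("male", True)):
        mh = m_height(ages, male)
        mw = m_weight(ages, male)
        for a, m in zip(ages, mh):
            rows.append(("height_for_age", "TOY", sex, a, 1.0, m, 0.035))
        for a, m in zip(ages, mw):
            rows.append(("weight_for_age", "TOY", sex, a, 0.5, m, 0.11))
        mbmi = mw / (mh / 100.0) ** 2
        for a, m in zip(ages, mbmi):
            rows.append(("bmi_for_age", "TOY", sex, a, 1.0, m, 0.08))
        # weight-for-length: median weight of the child whose median height is l
        lengths = np.linspace(44.0, 116.0, n_grid)
        hi = height_adult_cm + (1.0 if male else 0.0)
        with np.errstate(invalid="ignore"):
            t_of_l = np.where(
                lengths < hi, -np.log(np.clip((hi - lengths) / (hi - height_birth_cm), 1e-9, None)) / height_rate, 10.0
            )
        t_of_l = np.clip(t_of_l, -1.0, 10.0)
        mwl = m_weight(np.clip(t_of_l, -0.6, 8.0), male)
        for l, m in zip(lengths, mwl):
            rows.append(("weight_for_length", "TOY", sex, l, 1.0, m, 0.11))
        # preterm-role charts on a postmenstrual-age axis (20-52 weeks)
        pma_weeks = np.linspace(20.0, 52.0, 80)
        pma_years = pma_weeks / WEEKS_PER_YEAR
        flen = height_birth_cm + 0.9 * (pma_weeks - 40.0) + (0.5 if male else 0.0)
        fwt = (weight_birth_kg + (0.05 if male else 0.0)) * np.exp(0.09 * (pma_weeks - 40.0))
        for a, m in zip(pma_years, flen):
            rows.append(("height_for_age", "Fenton", sex, a, 1.0, m, 0.04))
        for a, m in zip(pma_years, fwt):
            rows.append(("weight_for_age", "Fenton", sex, a, 0.5, m, 0.16))
    frame = pd.DataFrame(rows, columns=CHART_COLUMNS)
    return ChartSet.from_frame(frame)


# ---------------------------------------------------------------------------
# Cohort-scale preset
# ---------------------------------------------------------------------------

#: Broken-stick class-mean shapes qualitatively mimicking the fitted
#: growth classes (e.g. "sharp decrease to low", "sharp increase to
#: high"); declared presets, not estimates.
_PRESET_KNOTS = (0.25, 0.75, 1.5, 2.5)
_PRESET_HEIGHT = np.array(
    [
        #  b0     b1     c@.25  c@.75  c@1.5  c@2.5
        [0.3, -6.0, 4.0, 1.6, 0.3, 0.1],    # sharp decrease to low
        [0.2, -1.6, 0.4, 0.6, 0.4, 0.2],    # gradual decrease to below expected
        [-0.5, -4.0, 6.0, -1.6, -0.3, -0.1],  # sharp decrease, sharp increase
        [0.0, 1.2, -2.0, -0.8, 1.2, 0.3],   # gradual increase, gradual decrease
    ]
)
_PRESET_WEIGHT = np.array(
    [
        [0.2, -4.5, 2.5, 1.4, 0.4, 0.2],    # gradual decrease to low
        [-0.2, -5.0, 6.5, -1.2, -0.2, -0.1],  # sharp decrease, sharp increase to expected
        [-0.1, 2.0, -2.2, -0.6, 0.6, 0.2],  # gradual increase, gradual decrease to expected
        [-0.8, 5.0, -3.2, -1.2, -0.4, -0.1],  # sharp increase to high
    ]
)


def dchs_like(n_subjects: int = 1143, seed: int = 0) -> SimSpec:
    """A preset reproducing the cohort's design scale.

    ~1,143 children, 16.7% preterm (late-preterm mode), 12.2% loss to
    follow-up, the 15-visit schedule, and four latent classes with
    5-51% proportions whose zHeight/zWeight broken-stick shapes mimic
    the fitted trajectory classes.
    """
    return SimSpec(
        n_subjects=n_subjects,
        class_proportions=(0.45, 0.17, 0.26, 0.12),
        knots={"zHeight": _PRESET_KNOTS, "zWeight": _PRESET_KNOTS},
        class_coef={"zHeight": _PRESET_HEIGHT, "zWeight": _PRESET_WEIGHT},
        re_sd=(0.45, 0.08),
        re_corr=-0.2,
        sigma={"zHeight": 0.35, "zWeight": 0.3},
        ltfu_fraction=0.122,
        preterm_fraction=0.167,
        seed=seed,
    )
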