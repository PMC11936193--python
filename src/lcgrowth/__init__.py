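"""Latent-class mixed models for standardized child growth trajectories.

The package implements an end-to-end growth-trajectory analysis for
longitudinal child anthropometry: LMS z-score standardization with
preterm reference switching, broken-stick (piecewise-linear spline)
mean models, univariate and joint bivariate latent class mixed models
(LCMM), class-number selection (BIC / entropy / ICL with a minimum
class-size rule), subsample stability validation, cross-tabulation of
class allocations, and abnormal-growth feature tables (rapid weight
gain, stunting, underweight, overweight).  A synthetic-cohort module
emulates the design of a South African birth cohort (~1,100 children
followed from birth to 5 years) so that every stage is testable
without access to restricted data.
"""

from lcgrowth.lms import (
    ChartRangeError,
    ChartSet,
    InvalidMeasurementError,
    ReferenceChart,
    lms_inverse,
    lms_zscore,
)
from lcgrowth.standardize import (
    AnthroRecord,
    UnresolvedReplicateError,
    reference_lookup,
    resolve_replicates,
    standardize_cohort,
)
from lcgrowth.basis import SplineSpec, broken_stick_basis, design_matrix, select_knots_aic
from lcgrowth.lcmm import (
    GrowthData,
    MixtureFit,
    MixtureSpec,
    ParameterSet,
    class_mean_trajectories,
    fit,
    marginal_loglik,
    posterior_probabilities,
)
from lcgrowth.selection import (
    FitStats,
    StabilityReport,
    fit_statistics,
    stability_resample,
    sweep_k,
)
from lcgrowth.allocation import (
    CrossTab,
    abnormal_flags,
    class_feature_table,
    crosstab,
    enrichment_flags,
    flag_ever,
    flag_rwg,
)
from lcgrowth.simulate import SimSpec, dchs_like, simulate_raw, simulate_zpanel, toy_reference

__version__ = "0.1.0"

__all__ = [
    "AnthroRecord",
    "ChartRangeError",
    "ChartSet",
    "CrossTab",
    "FitStats",
    "GrowthData",
    "InvalidMeasurementError",
    "MixtureFit",
    "MixtureSpec",
    "ParameterSet",
    "ReferenceChart",
    "SimSpec",
    "SplineSpec",
    "StabilityReport",
    "UnresolvedReplicateError",
    "abnormal_flags",
    "broken_stick_basis",
    "class_feature_table",
    "class_mean_trajectories",
    "crosstab",
    "dchs_like",
    "design_matrix",
    "enrichment_flags",
    "fit",
    "fit_statistics",
    "flag_ever",
    "flag_rwg",
    "lms_inverse",
    "lms_zscore",
    "marginal_loglik",
    "posterior_probabilities",
    "reference_lookup",
    "resolve_replicates",
    "select_knots_aic",
    "simulate_raw",
    "simulate_zpanel",
    "stability_resample",
    "standardize_cohort",
    "sweep_k",
    "toy_reference",
]
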