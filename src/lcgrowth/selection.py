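"""Class-number selection and subsample stability validation.

Candidate class counts are compared by BIC (lower is better), relative
entropy (posterior classification sharpness, 1 = crisp), and the
integrated classification likelihood ICL = BIC + 2 x total
classification entropy, subject to every class holding more than 5%
of the sample.  Chosen class counts are additionally validated by
refitting on ten random half-samples and checking that the class mean
curves reproduce the full-data curves after optimal label matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from lcgrowth.lcmm import GrowthData, MixtureFit, MixtureSpec, class_mean_trajectories, fit

MIN_CLASS_FRACTION = 0.05


@dataclass
class FitStats:
    """Model-choice statistics for one fitted class count."""

    K: int
    loglik: float
    n_params: int
    AIC: float
    BIC: float
    relative_entropy: float
    ICL: float
    class_proportions: np.ndarray
    min_class_fraction: float
    converged: bool


def classification_entropy(posteriors: np.ndarray) -> float:
    """Total classification entropy -sum_i sum_g p_ig ln p_ig (>= 0)."""
    p = np.clip(posteriors, 1e-300, 1.0)
    return float(-(p * np.log(p)).sum())


def fit_statistics(fit_result: MixtureFit, n_subjects: int | None = None) -> FitStats:
    """AIC/BIC, relative entropy and ICL for a fitted model.

    BIC uses the number of *subjects* (the independent sampling
    units), not observations.  Relative entropy is
    1 - E / (N ln K) with E the total classification entropy (defined
    as 1 for K=1); ICL = BIC + 2 E, so ICL >= BIC always.
    """
    N = n_subjects if n_subjects is not None else fit_result.n_subjects
    K = fit_result.spec.K
    ll = fit_result.loglik
    p = fit_result.n_params
    aic = -2.0 * ll + 2.0 * p
    bic = -2.0 * ll + p * np.log(N)
    ent = classification_entropy(fit_result.posteriors)
    rel_ent = 1.0 if K == 1 else 1.0 - ent / (N * np.log(K))
    icl = bic + 2.0 * ent
    props = np.bincount(fit_result.allocation, minlength=K) / max(N, 1)
    return FitStats(
        K=K,
        loglik=ll,
        n_params=p,
        AIC=aic,
        BIC=bic,
        relative_entropy=float(rel_ent),
        ICL=float(icl),
        class_proportions=props,
        min_class_fraction=float(props.min()),
        converged=fit_result.converged,
    )


@dataclass
class SweepResult:
    table: pd.DataFrame
    fits: dict  # K -> MixtureFit
    recommended_K: int | None
    notes: list = field(default_factory=list)


def sweep_k(
    data,
    base_spec: MixtureSpec,
    k_min: int = 1,
    k_max: int = 6,
    n_restarts: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> SweepResult:
    """Fit K = k_min..k_max and recommend the class count.

    The recommendation is the BIC-minimizing K among fits whose
    smallest class exceeds 5% of the sample; conflicts between BIC,
    entropy and ICL (and any withheld recommendation) are reported in
    ``notes`` rather than silently resolved.  All fits are retained.
    """
    if not k_max >= k_min >= 1:
        raise ValueError("need k_max >= k_min >= 1")
    if isinstance(data, pd.DataFrame):
        data = GrowthData.from_panel(data, base_spec.responses)
    fits = {}
    rows = []
    for K in range(k_min, k_max + 1):
        spec = MixtureSpec(
            responses=base_spec.responses,
            K=K,
            spline=base_spec.spline,
            random_effects=base_spec.random_effects,
            re_class_variance=base_spec.re_class_variance,
            link=base_spec.link,
        )
        f = fit(data, spec, n_restarts=(1 if K == 1 else n_restarts), seed=seed + K, **fit_kwargs)
        fits[K] = f
        st = fit_statistics(f)
        rows.append(
            {
                "K": K,
                "loglik": st.loglik,
                "n_params": st.n_params,
                "AIC": st.AIC,
                "BIC": st.BIC,
                "relative_entropy": st.relative_entropy,
                "ICL": st.ICL,
                "min_class_fraction": st.min_class_fraction,
                "converged": st.converged,
                "size_rule_ok": st.min_class_fraction > MIN_CLASS_FRACTION,
            }
        )
    table = pd.DataFrame(rows)
    recommended, notes = recommend_from_table(table)
    return SweepResult(table=table, fits=fits, recommended_K=recommended, notes=notes)


def recommend_from_table(table: pd.DataFrame):
    """Apply the selection rule to a k-sweep stats table.

    Recommends the BIC-minimizing K among rows passing the 5%
    class-size rule (non-convergent rows are dropped first but used
    as a fallback if nothing converged); disagreements between BIC,
    entropy and ICL are reported as notes.  Returns
    ``(recommended_K or None, notes)``.
    """
    notes = []
    eligible = table[table["size_rule_ok"] & table["converged"]]
    if eligible.empty:
        eligible = table[table["size_rule_ok"]]
    if eligible.empty:
        notes.append("no class count satisfies the 5% minimum class-size rule; recommendation withheld")
        return None, notes
    recommended = int(eligible.loc[eligible["BIC"].idxmin(), "K"])
    # relative entropy is 1 at K=1 by definition, so compare it among K >= 2
    ent_rows = eligible[eligible["K"] > 1] if (eligible["K"] > 1).any() else eligible
    k_ent = int(ent_rows.loc[ent_rows["relative_entropy"].idxmax(), "K"])
    k_icl = int(eligible.loc[eligible["ICL"].idxmin(), "K"])
    if len({recommended, k_ent, k_icl}) > 1:
        notes.append(f"criteria disagree: BIC -> K={recommended}, entropy -> K={k_ent}, ICL -> K={k_icl}")
    return recommended, notes


# ---------------------------------------------------------------------------
# Stability via half-sample refits
# ---------------------------------------------------------------------------


def match_classes(curves_a: np.ndarray, curves_b: np.ndarray):
    """Best label permutation of ``curves_a`` onto ``curves_b`` by curve RMSE.

    Curves are (K, n_grid) or (K, n_grid * n_responses) stacks.
    Returns (permutation, rmse): exhaustive over K! permutations, so
    matching is symmetric in its arguments.
    """
    K = curves_a.shape[0]
    best_perm, best_rmse = None, np.inf
    for perm in permutations(range(K)):
        rmse = float(np.sqrt(np.mean((curves_a[list(perm)] - curves_b) ** 2)))
        if rmse < best_rmse:
            best_rmse, best_perm = rmse, perm
    return best_perm, best_rmse


def _stacked_curves(fit_result: MixtureFit, grid) -> np.ndarray:
    curves = class_mean_trajectories(fit_result, grid)
    return np.hstack([curves[r] for r in fit_result.spec.responses])


@dataclass
class StabilityReport:
    """Half-sample refit stability of a chosen class count."""

    K: int
    rmse: list  # matched curve RMSE per replicate (NaN when non-convergent)
    converged: list
    pass_fraction: float
    threshold: float
    replicate_curves: list  # per replicate: (K, grid*responses) matched curves


def stability_resample(
    data,
    spec: MixtureSpec,
    full_fit: MixtureFit,
    reps: int = 10,
    frac: float = 0.5,
    seed: int = 0,
    n_restarts: int = 5,
    rmse_threshold: float = 0.25,
    grid=None,
    **fit_kwargs,
) -> StabilityReport:
    """Refit on random half-samples and compare matched class-mean curves.

    Each replicate draws ``floor(frac * N)`` subjects without
    replacement, refits the model, matches replicate classes to the
    full-data classes by the label permutation minimizing mean curve
    RMSE on an age grid over [0, 5], and passes when the matched RMSE
    is below ``rmse_threshold`` z-units.  Non-convergent replicates
    are recorded as failures, not dropped.
    """
    if isinstance(data, pd.DataFrame):
        data = GrowthData.from_panel(data, spec.responses)
    if grid is None:
        grid = np.linspace(0.0, 5.0, 26)
    full_curves = _stacked_curves(full_fit, grid)
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=reps)
    rmses, conv, matched_curves = [], [], []
    n_take = int(np.floor(frac * data.n_subjects))
    for rep in range(reps):
        rng = np.random.default_rng(rep_seeds[rep])
        if frac >= 1.0:
            sub = data
        else:
            chosen = rng.choice(data.subjects, size=n_take, replace=False)
            sub = data.subset(chosen)
        try:
            f = fit(sub, spec, n_restarts=n_restarts, seed=int(rep_seeds[rep]), **fit_kwargs)
        except Exception:
            rmses.append(float("nan"))
            conv.append(False)
            matched_curves.append(None)
            continue
        conv.append(bool(f.converged))
        if not f.converged:
            rmses.append(float("nan"))
            matched_curves.append(None)
            continue
        curves = _stacked_curves(f, grid)
        perm, rmse = match_classes(curves, full_curves)
        rmses.append(rmse)
        matched_curves.append(curves[list(perm)])
    passes = [c and np.isfinite(r) and r < rmse_threshold for c, r in zip(conv, rmses)]
    return StabilityReport(
        K=spec.K,
        rmse=rmses,
        converged=conv,
        pass_fraction=float(np.mean(passes)),
        threshold=rmse_threshold,
        replicate_curves=matched_curves,
    )
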