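"""End-to-end analysis pipeline: simulate/load -> standardize -> fit -> compare.

Runs the full trajectory analysis behind one reproducible config:
standardize raw measurements (or generate a synthetic cohort),
fit univariate latent-class models for zHeight, zWeight, zBMI and
zWFH plus the joint bivariate zHeight+zWeight model across a range of
class counts, select the class number, validate it by half-sample
stability, cross-tabulate allocations between models, and tabulate
abnormal-growth features by class.  A manifest records the config
hash, seeds and library versions so every output is regenerable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lcgrowth import __version__
from lcgrowth.allocation import abnormal_flags, class_feature_table, crosstab, enrichment_flags
from lcgrowth.basis import SplineSpec
from lcgrowth.lcmm import GrowthData, MixtureSpec, class_mean_trajectories, fit
from lcgrowth.lms import ChartSet
from lcgrowth.selection import fit_statistics, stability_resample, sweep_k
from lcgrowth.simulate import dchs_like, simulate_raw, toy_reference
from lcgrowth.standardize import standardize_cohort, write_zpanel_csv

log = logging.getLogger("lcgrowth.pipeline")

UNIVARIATE_RESPONSES = ("zHeight", "zWeight", "zBMI", "zWFH")
JOINT = ("zHeight", "zWeight")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # inputs: either a simulation preset or panel/chart paths
    preset: str = "dchs-like"
    n_subjects: int = 1143
    panel_path: str | None = None
    charts_path: str | None = None
    # model settings
    responses: tuple = UNIVARIATE_RESPONSES
    joint: bool = True
    knots: dict = field(default_factory=dict)  # response -> knot list override
    k_min: int = 1
    k_max: int = 6
    n_restarts: int = 30
    stability_reps: int = 10
    stability_frac: float = 0.5
    z_limit: float = 6.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.responses = tuple(cfg.responses)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["responses"] = list(self.responses)
        return d

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("inputs")
def _acquire_inputs(cfg: PipelineConfig, out: Path):
    if cfg.panel_path is not None:
        panel = pd.read_csv(cfg.panel_path)
        charts = ChartSet.from_csv(cfg.charts_path)
        truth = None
    else:
        if cfg.preset != "dchs-like":
            raise ValueError(f"unknown preset {cfg.preset!r}")
        spec = dchs_like(n_subjects=cfg.n_subjects, seed=cfg.seed)
        charts = toy_reference()
        cohort = simulate_raw(spec, charts)
        panel = cohort.raw_panel
        truth = cohort.true_labels
        panel.to_csv(out / "raw_panel.csv", index=False)
        charts.to_csv(out / "charts.csv")
        truth.rename("true_class").to_csv(out / "true_labels.csv")
    return panel, charts, truth


@_stage("standardize")
def _standardize(cfg, panel, charts, out: Path):
    zpanel, exclusions = standardize_cohort(panel, charts, z_limit=cfg.z_limit)
    write_zpanel_csv(zpanel, out / "zpanel.csv")
    exclusions.to_csv(out / "exclusions.csv", index=False)
    for reason, n in exclusions["reason"].value_counts().items():
        log.debug("excluded %d observations: %s", n, reason)
    return zpanel


def _model_name(responses) -> str:
    return "+".join(responses)


@_stage("fit")
def _fit_one_model(cfg: PipelineConfig, zpanel, responses, out: Path):
    name = _model_name(responses)
    mdir = out / name
    mdir.mkdir(parents=True, exist_ok=True)
    spline = {r: SplineSpec(tuple(cfg.knots[r])) for r in responses if r in cfg.knots}
    base = MixtureSpec(responses=responses, K=1, spline=spline or None)
    data = GrowthData.from_panel(zpanel, responses)
    sweep = sweep_k(
        data, base, k_min=cfg.k_min, k_max=cfg.k_max, n_restarts=cfg.n_restarts, seed=cfg.seed
    )
    sweep.table.to_csv(mdir / "ksweep.csv", index=False)
    chosen = sweep.recommended_K if sweep.recommended_K is not None else cfg.k_min
    best = sweep.fits[chosen]
    best.to_json(mdir / f"fit_K{chosen}.json")
    best.posteriors_frame().to_csv(mdir / "posteriors.csv", index=False)
    grid = np.linspace(0.0, 5.0, 51)
    curves = class_mean_trajectories(best, grid)
    curve_rows = []
    for r, mat in curves.items():
        for g in range(mat.shape[0]):
            for t, v in zip(grid, mat[g]):
                curve_rows.append({"response": r, "class": g + 1, "age_years": t, "value": v})
    pd.DataFrame(curve_rows).to_csv(mdir / "curves.csv", index=False)
    stab = None
    if chosen > 1:
        stab = stability_resample(
            data,
            best.spec,
            best,
            reps=cfg.stability_reps,
            frac=cfg.stability_frac,
            seed=cfg.seed + 1,
            n_restarts=max(2, cfg.n_restarts // 4),
        )
        pd.DataFrame(
            {"replicate": range(1, len(stab.rmse) + 1), "matched_rmse": stab.rmse, "converged": stab.converged}
        ).to_csv(mdir / "stability.csv", index=False)
    stats = fit_statistics(best)
    log.info(
        "%s: chose K=%d (BIC %.1f, entropy %.3f, stability pass %.0f%%)",
        name, chosen, stats.BIC, stats.relative_entropy,
        100 * (stab.pass_fraction if stab else float("nan")),
    )
    return best, sweep, stab


@_stage("allocations")
def _allocation_tables(fits: dict, zpanel, out: Path):
    cdir = out / "crosstabs"
    cdir.mkdir(parents=True, exist_ok=True)
    labels = {
        name: pd.Series(f.allocation + 1, index=f.subjects, name=name) for name, f in fits.items()
    }
    pairs = []
    joint_name = _model_name(JOINT)
    if joint_name in labels:
        for uni in ("zHeight", "zWeight", "zBMI", "zWFH"):
            if uni in labels:
                pairs.append((joint_name, uni))
    if "zBMI" in labels and "zWFH" in labels:
        pairs.append(("zBMI", "zWFH"))
    tables = {}
    for a, b in pairs:
        common = labels[a].index.intersection(labels[b].index)
        ct = crosstab(labels[a].loc[common], labels[b].loc[common])
        key = f"{a}_vs_{b}"
        ct.counts.to_csv(cdir / f"{key}_counts.csv")
        ct.row_pct.to_csv(cdir / f"{key}_row_pct.csv")
        enrichment_flags(ct).to_csv(cdir / f"{key}_enrichment.csv", index=False)
        tables[key] = ct
    return tables


@_stage("features")
def _feature_tables(fits: dict, zpanel, out: Path):
    fdir = out / "features"
    fdir.mkdir(parents=True, exist_ok=True)
    flags = abnormal_flags(zpanel)
    flags.to_csv(fdir / "abnormal_flags.csv", index=False)
    tables = {}
    feature_by_model = {
        "zWeight": ("rwg", "ever_underweight", "ever_overweight"),
        "zHeight": ("ever_stunted",),
    }
    for model, feats in feature_by_model.items():
        if model not in fits:
            continue
        f = fits[model]
        labels = pd.Series(f.allocation + 1, index=f.subjects)
        for feat in feats:
            tab = class_feature_table(labels, flags, feat)
            tab.to_csv(fdir / f"{model}_{feat}.csv", index=False)
            tables[f"{model}_{feat}"] = tab
    return tables


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Any stage failure halts with a stage-tagged error; outputs written
    by earlier stages are preserved in the run directory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, charts, truth = _acquire_inputs(cfg, out)
    zpanel = _standardize(cfg, panel, charts, out)

    fits = {}
    model_sets = [(r,) for r in cfg.responses]
    if cfg.joint:
        model_sets.append(JOINT)
    for responses in model_sets:
        best, sweep, stab = _fit_one_model(cfg, zpanel, responses, out)
        fits[_model_name(responses)] = best
    _allocation_tables(fits, zpanel, out)
    _feature_tables(fits, zpanel, out)

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "versions": {
            "lcgrowth": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "models": {name: {"K": f.spec.K, "loglik": f.loglik, "converged": bool(f.converged)} for name, f in fits.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
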