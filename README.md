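# lcgrowth

Latent-class mixed models for standardized child growth trajectories.

## The problem

Child growth in the first five years is heterogeneous: some children
falter early and catch up, some drift steadily below the expected
height or weight for their age and sex, some gain weight rapidly in
infancy and stay heavy.  Identifying these *latent growth classes* —
groups of children sharing a trajectory shape — matters for flagging
risk (stunting, rapid weight gain, over/underweight) and timing
interventions.  This package implements the full analysis for
longitudinal birth-cohort anthropometry of the kind collected by the
Drakenstein Child Health Study (DCHS): ~1,100 children measured at
birth, 6/10/14 weeks, 6/9/12 months and then six-monthly to age 5,
with duplicated technical measurements, a preterm subgroup, and loss
to follow-up.  Because such cohort data are not public, the package
ships a first-class synthetic-cohort generator that emulates the
design, so every stage is exercised and tested end to end.

## The model

Measurements are first converted to z-scores with the LMS method:
given a reference chart triple (L, M, S) at the child's age (or
length) and sex,

    z = ((x/M)^L − 1) / (L·S)    (L ≠ 0;  ln(x/M)/S when L = 0).

Preterm children (< 37 weeks gestation) are standardized against a
preterm reference indexed by postmenstrual age until 50 weeks PMA,
then against the at-term reference with gestational-age-corrected
ages until age 2.  Responses: zHeight, zWeight, zBMI, zWFH.

Each response's mean trajectory is a broken-stick (piecewise-linear
spline) function of age.  A K-class latent class mixed model (LCMM)
assumes child i belongs to an unobserved class g with probability
π_g = softmax(ξ)_g and, given the class,

    Y_i | g  ~  N( X_i β_g ,  Z_i B Z_iᵀ + σ² I ),

where X_i stacks broken-stick basis rows [1, t, (t−κ₁)₊, …], β_g are
class-specific fixed effects, and Z_i b_i is a subject-level random
intercept + age slope with covariance B shared across classes.  The
joint bivariate model couples zHeight and zWeight through shared
class membership while giving each response its own latent structure
(basis, random effects, residual variance).  Estimation is maximum
likelihood: EM warm-ups over multiple perturbed restarts, quasi-Newton
refinement with analytic gradients, classes reported sorted by
descending π̂.  The number of classes is chosen by sweeping K = 1..6
and taking the lowest BIC subject to every class exceeding 5% of the
sample, with relative entropy and ICL reported alongside, and the
choice validated by ten half-sample refits whose matched class curves
must reproduce the full-data curves.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic cohort (each writes its tables under `results/analysis/`):

```bash
cd analysis
python 01_simulate_cohort.py   # 1,143 children, raw duplicated measurements
python 02_standardize.py       # LMS z-scores with reference switching
python 03_select_knots.py      # broken-stick knots by AIC (K=1 fits)
python 04_fit_classes.py       # LCMM sweep K=1..5, univariate + joint
python 05_stability.py         # half-sample stability of the chosen K
python 06_allocations_features.py  # cross-tabs + abnormal-growth tables
python 07_validation.py        # recovery/selection/stability harnesses
```

Output of `04_fit_classes.py` on the default seed:

```
zHeight: recommended K = 3 (BIC 19459.1, class proportions [0.44, 0.281, 0.278])
zWeight: recommended K = 4 (BIC 14762.3, class proportions [0.429, 0.286, 0.179, 0.107])
zHeight+zWeight: recommended K = 4 (BIC 31463.4, class proportions [0.432, 0.28, 0.176, 0.112])
```

The generating truth has four classes with proportions
(0.45, 0.17, 0.26, 0.12): zWeight and the joint model recover the
class count and proportions; zHeight merges two classes whose height
profiles are close — exactly the kind of response-dependent K the
method is meant to surface.  `05_stability.py` then reports

```
zWeight K=4: pass fraction 1.00 (threshold 0.25 z)
```

i.e. all ten half-sample refits reproduce the full-data class curves
within 0.25 z after label matching, and `06_allocations_features.py`
cross-tabulates allocations (joint class 4 children are 92.9% in
zWeight class 4, against a 10.4% cohort marginal — a strongly enriched
cell) and profiles abnormal growth, e.g. rapid weight gain (zWeight
gain ≥ 0.67 from birth to nine months) peaking at 100% in the
sharp-increase class against an 18.1% cohort rate.

The same machinery is available as a library (`import lcgrowth`) and
as a CLI (`lcgrowth simulate|standardize|fit|select-k|stability|crosstab|flags|run-all`).

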