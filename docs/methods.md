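# Methods

This note documents the models, conventions and design choices behind
`lcgrowth`, in the order the pipeline applies them.

## Standardization

**LMS transform.** A measurement x is standardized against a sex- and
age-specific reference triple (L, M, S) as
z = ((x/M)^L − 1)/(L·S), with the L → 0 limit ln(x/M)/S. The
implementation uses the `expm1`/`log1p` forms so the two branches agree
to ~1e−9 near L = 0, and the inverse transform round-trips to < 1e−9
over the realistic parameter range (property-tested). Chart tables are
long-form CSV (measure, source, sex, axis_value, L, M, S); L, M, S are
interpolated linearly in the axis variable within sex and never
extrapolated — out-of-range lookups become logged per-observation
exclusions, not errors.

**Replicate resolution.** Height and weight are measured twice per
visit; the pair is accepted when the two values agree within 0.5 cm
(height) or 0.1 kg (weight), in which case the *first* value is used;
otherwise the third measurement is used. "Within" is read inclusively,
with a ~1e−9 relative epsilon so decimal tolerances behave as written
under binary floating point. A discordant pair with no third value is
an unresolved-replicate exclusion.

**Reference switching for preterm children.** Children born before 37
completed weeks are standardized against a preterm-role chart indexed
by postmenstrual age (PMA = gestational age + chronological age) while
PMA < 50 weeks, and against the at-term chart afterwards. From the
handover until age 2, the at-term lookup uses a gestational-age-
corrected age: chronological age minus (40 − GA) weeks, with 40 weeks
as the term anchor (the correction the convention implies but rarely
spells out), floored at zero and converted at 365.25/7 weeks per year.
From age 2 onward the chronological age is used. Term children always
use the at-term chart. zBMI (weight / height² in kg/m²) and zWFH
(weight against a length-indexed chart) are standardized against the
at-term (WHO-role) charts only, at the same corrected age.

**Plausibility filter.** Observations with |z| > 6 after
standardization are treated as instrumental/measurement error and
excluded with a logged reason (the WHO flagging convention; the
threshold is a keyword argument). The standardizer guarantees
emitted + excluded = visits × responses — no silent drops.

## Broken-stick mean trajectories

Each response's population trajectory is piecewise linear in age with
knots κ₁ < … < κ_J, in the truncated-power parameterization
[1, t, (t−κ₁)₊, …, (t−κ_J)₊], so coefficient j+2 is the slope change
at κ_j. The basis is continuous at knots (tested to 1e−10), reproduces
any piecewise-linear function with those breaks exactly, and has full
column rank iff every inter-knot interval contains data (a rank
warning is raised otherwise). Packaged default knots: (0.25, 0.75,
1.5, 2.5) years for zHeight/zWeight and (0.25, 1.0, 2.5) for
zBMI/zWFH — three to four knots inside [0.25, 2.5] years, where visit
density is highest and trajectory structure changes fastest; configs
can override per response. Knot sets are compared by the AIC of
single-class (K = 1) mixed-model fits, and a denser "extended" set
(0.25, 0.75, 1, 1.5, 2, 3, 4) is provided for the sensitivity check
that class curves are insensitive to knot placement (asserted to agree
within 0.15 z after label matching).

## The latent class mixed model

For subject i in class g (probability π_g = softmax(ξ)_g; the class
model is an intercept-only multinomial — no covariates):

Y_i | g ~ N(X_i β_g, Σ_i),  Σ_i = ω_g² Z_i B Z_iᵀ + σ² I,

with B = L Lᵀ the random intercept + age-slope covariance (a
random-intercept-only option exists). The marginal log-likelihood is
ℓ = Σ_i log Σ_g π_g φ(Y_i; X_i β_g, Σ_i), evaluated per
observation-pattern block (subjects sharing a visit-age vector share
one Cholesky factorization) with log-sum-exp stabilized posteriors.

**Random-effect structure across classes.** By default B is shared
across classes (`re_class_variance="shared"`); a per-class
proportional scale ω_g (reference class fixed at 1) is available
behind a flag. The shared default is the common LCMM convention and
keeps the within-class covariance identical across classes, which both
stabilizes estimation and speeds it up.

**Joint bivariate model.** zHeight and zWeight share the latent class;
conditional on the class the two responses are independent, each with
its own basis, B, and σ — the within-class density factorizes across
responses. With one class this degenerates exactly to the sum of the
two univariate log-likelihoods (tested).

**Link functions.** The default link is the identity — the responses
are already z-scores. Two estimated links are provided for sensitivity
analysis, both parameterizing a transform of the observed value to the
latent scale with the latent residual SD fixed at 1 for
identifiability: a linear link (location + positive scale; an exact
reparameterization of the identity model, and tested to reach the same
maximized likelihood) and a monotone cubic spline link with three
equally spaced interior knots (integrated quadratic B-spline basis
with positive weights, Jacobian included in the likelihood). The
estimated links use numerical gradients and are outside the default
analysis path.

**Estimation.** (1) A K = 1 fit (EM + refinement) anchors the
initialization. (2) Restarts: the first candidate splits subjects into
K groups by their mean observed level and initializes each class by
group-wise OLS; the remaining candidates perturb the K = 1 fixed
effects with N(0, 0.5²) noise. The K = 1 random-effect covariance is
shrunk by 1/√K in these starts — between-class separation inflates the
single-class intercept variance, and starting EM there lets the random
effects swallow the class structure (a collapsed local optimum).
(3) Each candidate gets a short monotone EM warm-up (30 iterations);
the best by log-likelihood is run to EM convergence (Δℓ < 1e−6), then
refined by L-BFGS-B over all parameters (log-Cholesky for B, log σ),
with analytic gradients on the default path (shared B, identity
links; verified against numerical differentiation to 1e−6). Refinement
alternates with EM polish rounds until the gradient max-norm falls
below 1e−4; `converged` certifies gradient max-norm < 1e−4 *and* final
EM gain < 1e−6. The EM itself is a generalized EM: π and β update in
closed form (posterior-weighted GLS), then B and σ² update from the
conditional random-effect moments at the refreshed posteriors; each
step is a coordinate maximization of an EM minorant, so the
log-likelihood never decreases (property-tested at 1e−8). Everything
is driven by one integer seed; refitting the same data and seed is
bit-identical. Default restarts: 30 (the warm-up makes extra restarts
cheap); the analysis drivers and harnesses use 4–5, which suffices at
their separation levels. Classes are reported sorted by descending π̂;
MAP allocation ties break toward the lower class index. A fit where
every restart fails returns a diagnostic failure object rather than
raising; a class with π̂ < 1/N is flagged as empty.

**Floors and guards.** σ ≥ 1e−4 (noiseless data drive it to the
floor), Cholesky diagonals ≥ 1e−6, B symmetrized with 1e−10 jitter
before factorization; non-finite trial parameters during line search
are treated as infeasible (objective 1e12), never crashes.

## Class-number selection

For each fitted K: AIC = −2ℓ + 2p; BIC = −2ℓ + p ln N with N = number
of **subjects** (the independent units), not observations;
relative entropy = 1 − E/(N ln K) where E = −Σ_i Σ_g p_ig ln p_ig
(defined as 1 at K = 1; 1 means crisp assignment, 0 uninformative);
ICL = BIC + 2E ≥ BIC. The recommendation is the BIC-minimizing K among
fits whose smallest class exceeds 5% of the sample; entropy (compared
among K ≥ 2, since it is 1 at K = 1 by definition) and ICL
disagreements are reported as notes, never silently resolved, and if
no K passes the size rule the recommendation is withheld while the
full table is still returned. Entropy and ICL are defined here
explicitly because naming conventions vary across software; results
are labeled with these definitions.

## Stability validation

The chosen K is refit on 10 random half-samples (⌊N/2⌋ subjects
without replacement, seeds spawned from a master seed). Replicate
class-mean curves are matched to the full-data curves by the label
permutation minimizing mean curve RMSE on a 26-point age grid over
[0, 5] (exhaustive over K! ≤ 720 permutations, hence symmetric in its
arguments); a replicate passes when the matched RMSE is below 0.25 z.
The pass fraction makes quantitative a check that is usually done by
eye (overplotting replicate curves); 0.25 z is roughly the visual
width at which overplotted trajectories stop looking like "the same
class". Non-convergent replicates count as failures rather than being
dropped.

## Allocation comparison and abnormal-growth features

Cross-tabulations report counts and row percentages; a cell is flagged
as enriched when its row percentage exceeds the column's cohort
marginal percentage, with the difference reported as the effect size.
Abnormal-growth flags per child: rapid weight gain (RWG) is a zWeight
gain ≥ 0.67 between birth and nine months — birth anchored at the
first observation with age ≤ 0.02 y, nine months at the observation
nearest 0.75 y within [0.6, 0.9] y; the ≥ (inclusive) reading follows
the definition's "equal or greater" wording. Ever-stunted /
underweight / overweight use strict inequalities exactly as
conventionally printed (any zHeight < −2 / zWeight < −2 /
zWeight > 2 before age 5; a constant −2.0 series is *not* stunted).
Children missing an anchor visit (or with no usable observations) have
an explicitly undefined flag and are excluded from denominators; the
feature tables' class totals therefore sum to the number of children
with defined flags. Percentages in feature tables are rounded half-up
to one decimal.

The package also ships the printed allocation and feature count tables
of the published DCHS analysis (`lcgrowth.published`) as fixed
reference inputs for validating the tabulation arithmetic. Two printed
percentages there disagree with their own printed counts by slightly
more than half a unit in the last digit (3/242 printed as 1.3%, and
61/112 printed as 55%); the counts are encoded as printed and the
comparison bands widened for exactly those two cells. Likewise the
published feature table uses denominators (N = 1139, one class of 584)
that differ from the cross-tabulation totals (N = 1136, 581); each
table is reproduced exactly as printed, unreconciled.

## Synthetic cohort generator

The generator emulates the cohort design the analysis assumes:

* **Schedule**: 15 visits — birth, 6/10/14 weeks, 6/9/12 months, then
  6-monthly to 5 years.
* **Classes**: labels ~ Categorical(π); per class and response a
  broken-stick mean curve; subject random intercept + slope (explicit
  2×2 Cholesky factor, exact for degenerate zero-SD settings) and
  i.i.d. Gaussian residuals.
* **Dropout**: completely at random across subjects (12.2% by
  default), with the dropout visit weighted toward infancy
  (exp(−2t) weights — most loss before 6 months) and monotone: once
  gone, gone. Informative dropout is out of scope.
* **Preterm**: 16.7% by default; gestational ages triangular on
  [28, 37) weeks with a late-preterm mode, term uniform on [37, 42],
  half-week resolution.
* **Raw layer**: generating z-values are inverted through the same
  chart and reference-switching rules the standardizer will apply,
  then jittered with replicate noise (0.15 cm / 0.03 kg SD); whenever
  the two replicates disagree beyond tolerance — or with a small
  forced-disagreement probability — a third replicate is emitted, as
  in the measurement protocol. With replicate noise zero the
  standardizer recovers the generating z to < 1e−6 (in practice
  ~1e−14), which is the round-trip oracle for the whole
  standardization stage.
* **Toy charts**: smooth synthetic LMS references (saturating median
  growth curves, constant L and S, small sex offsets) for all four
  measures plus preterm-role charts on a PMA axis. They are stand-ins
  with plausible shapes, not official reference values, and the
  package deliberately does not ship real WHO/Fenton tables — users
  with licensed charts supply them as CSV.
* The `dchs_like` preset reproduces the design scale: 1,143 children,
  four classes with proportions (0.45, 0.17, 0.26, 0.12) whose
  zHeight/zWeight shapes qualitatively mimic the published classes
  (declared presets, not estimates of the published coefficients).

What the generator does *not* emulate: informative dropout,
measurement drift with age, seasonal effects, the length-to-standing-
height transition at 18 months, or covariate structure (HIV exposure,
socio-economic status). Passing tests therefore demonstrate
correctness of the machinery under the stated model, not robustness to
these real-data features.

## Validation harnesses and problem sizes

The recovery/selection/stability harnesses (shared by the test suite,
`scripts/acceptance.py` and `analysis/07_validation.py`) use a
three-class cohort at n = 600, π = (0.5, 0.3, 0.2), with class-mean
curves separated by at least 1.5 z at every age. The generating knots
are (0.5, 1.5, 3.0): each inter-knot segment spans several scheduled
visits, so the truncated-power coefficients are individually
well-conditioned — with knots at 0.25 y only four visits precede the
first knot and the global slope and first slope-change become nearly
collinear, making per-coefficient tolerances meaningless even for a
perfect estimator (the class *curves* remain precise either way).
Noise is moderate (residual SD 0.15 z, random intercept/slope SD
0.25/0.05 z), putting the fixed-effect sampling error well inside the
±0.1 acceptance band so that estimation bias would be visible.
Selection sweeps K = 1..5 at this n; stability uses 10 half-sample
refits. These sizes keep the full validation under a few minutes on a
single CPU while remaining at the design scale of the cohort.

## Known limitations

* The EM/quasi-Newton optimizer guarantees a local optimum only; the
  quantile-split start plus perturbed restarts is effective at the
  separations studied here, but poorly separated classes may need more
  restarts.
* Cross-response random-effect correlation in the joint model is not
  estimated: conditional on the class, the two responses' latent
  structures are independent.
* The proportional per-class RE scale ω_g is refined only in the
  quasi-Newton stage (EM holds it fixed), so it converges more slowly
  than the shared default.
* The estimated link functions are sensitivity tools, not the default
  path, and use numerical gradients.
* BIC with N = subjects, the relative-entropy normalization and
  ICL = BIC + 2E are stated conventions; other software may define
  these differently, so cross-package comparisons should compare ℓ and
  p, not the derived criteria.
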