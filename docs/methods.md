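# Methods

## The two scales and the estimand problem

Illumina-style methylation arrays report, per CpG site *i*, a methylated
and an unmethylated intensity. The **Beta-value**

    Beta_i = max(meth, 0) / (max(meth, 0) + max(unmeth, 0) + 100)

is the fraction of methylated signal — directly interpretable as percent
methylation, bounded in [0, 1) (the +100 offset keeps it below 1, values
read from processed files can still touch both ends). Because Beta-values
are beta-distributed and heteroscedastic, analysis pipelines work on the
**M-value**, the base-2 logit

    M_i = log2(Beta_i / (1 − Beta_i)),      Beta_i = 2^M_i / (1 + 2^M_i),

which is approximately normal and suits Gaussian linear modelling. The
transforms are exact inverses of each other pointwise — but **differences
do not transform**: the same ΔBeta corresponds to many ΔM (and vice
versa) depending on the baseline. The worked-example table
(`methylestimand.table4`) makes this concrete: a constant ΔBeta of 0.10
spans ΔM from 0.58 to 6.81. A treatment coefficient from an M-scale
regression is therefore not a reportable effect size by itself.

Two distinct logits appear and are named apart: the base-2 *M-logit*
(`beta_to_m` / `m_to_beta`) and the natural-log logit whose inverse
(`inverse_logit`) back-transforms beta-regression coefficients. They
differ by a factor ln 2 in the exponent and must never be interchanged.

## The envelope (mustache) of ΔBeta given ΔM

For a fixed ΔM ≥ 0 the attainable ΔBeta is an interval. The maximum has a
closed form: write the pair as (m, m + ΔM); the difference
`m_to_beta(m + ΔM) − m_to_beta(m)` is maximised at the pair symmetric
about zero, m = −ΔM/2, giving
`delta_beta_max(ΔM) = m_to_beta(ΔM/2) − m_to_beta(−ΔM/2)` — e.g. 0.6996
for ΔM = 5. The minimum depends on how close to 0/1 the baseline may go
and is reported as grid-dependent: `delta_beta_range` sweeps 10⁵ baselines
over [0.001, 0.999] by default (ΔM = 5 then reaches down to ≈ 0.03;
admitting baselines nearer 0 pushes it towards 0). An infeasible
combination (ΔM too large for the bounds) raises an explicit
empty-envelope error rather than returning zero.

### Printed-table conventions

M-values are displayed at 2 decimals, back-transformed Beta-values at 3.
The printed ΔM column of the worked-example table is the difference of
the *rounded* group M-values — the number a reader reconstructs from the
table — and can differ by one unit in the last digit from the rounded
full-precision difference (e.g. baseline 0.201: 0.776 at full precision,
printed 0.77 = −1.22 + 1.99). Both columns are emitted. The default grid's
last row mirror-caps the treatment value at 0.999 (the reflection of the
opening 0.001 row); the actual difference 0.098 prints as 0.10 and the row
is marked `capped`.

## Synthetic cohorts

`simulate_cohort` draws a two-group (Placebo/Treatment) cohort on the M
scale from

    M = β0 + β1·Grp + β3·(Age − 50) + β4·(Sex − 0.3) + ε,  ε ~ N(0, σ²)

with the predefined effect specified on the Beta scale and mapped through
the logit: β0 = beta_to_m(beta0_placebo) and
ΔM_total = beta_to_m(beta0 + ΔBeta) − β0. A **confounder fraction**
c ∈ [0, 1) diverts part of the effect to covariates: β1 = (1 − c)·ΔM_total
while Age (N(50, 8²) vs N(55, 8²) years) and Sex (Bernoulli 0.3 vs 0.6)
are group-imbalanced and their coefficients are scaled so each carries
half of c·ΔM_total in expectation (`confounder_split` adjustable), in the
same direction as the treatment effect. Centring the covariates at their
placebo population values keeps β0 equal to the placebo-group mean for
every c, and the *raw* expected between-group difference equals ΔM_total
regardless of c — only its attribution changes, which is precisely what an
unadjusted estimate cannot detect.

Defaults: n = 500 per group, σ = 0.5 on the M scale. Replicate studies
default to desk scale (200 replicates of n = 200 per group; a
`--paper-scale` flag restores 5000 × 1000) so the full analysis suite runs
in about a minute on one CPU; orderings and signs are stable at either
scale. For Beta-scale outcomes (`simulate_beta_outcome`, used by the
convergence study) values are drawn from beta distributions with
group-specific means and common precision φ = 30 (SD ≈ 0.05 at a mean of
0.1 — a typical between-sample spread for an array CpG).
`fixture_matrix` emulates the shape of processed array data: a
configurable fraction of CpG rows hypo- (mean < 0.1) or hypermethylated
(> 0.9), the rest mid-range.

What the generator does **not** emulate: probe-type effects, batch/chip
structure, cell-composition mixtures, spatial correlation along the
genome, or missing values. Passing simulations therefore demonstrate
estimand algebra and estimator behaviour under clean confounding, not
robustness to the full messiness of real arrays.

## The four reporting approaches

1. **Gaussian on Beta-values** (`fit_gaussian_beta`): OLS per CpG on the
   Beta scale; the coefficient is a ΔBeta, but fits near the boundary are
   biased and may predict outside [0, 1] (flagged per CpG, not fatal).
2. **Beta regression** (`fit_beta_regression`): maximum likelihood with a
   natural-log logit mean link and constant precision. The estimand is
   exp(coefficient) — a methylation-*odds ratio*, not a difference.
3. **Raw Beta difference** (`raw_beta_diff`): difference of group
   Beta-value means, p-value taken from the companion unadjusted M-scale
   fit. Unadjusted by construction; its bias under confounding is the
   central negative result.
4. **Intercept method** (`fit_m_with_intercept`): covariate-adjusted OLS
   on M-values keeping the intercept; the estimand is
   `m_to_beta(β0 + β1) − m_to_beta(β0)`, the confounder-adjusted ΔBeta.

Mass OLS is vectorised (one linear solve per matrix, exact t-tests from
the per-CpG residual variance) — numerically identical to a per-CpG
`statsmodels` OLS, which a test verifies independently. No empirical-Bayes
variance moderation is applied: moderation changes p-values, never the
coefficient estimates this package is about; p-values here are the plain
OLS ones, with optional Benjamini–Hochberg adjustment as post-processing.

**Covariate coding.** The treatment indicator is 0/1 with Placebo as
reference. Age is centred at the placebo-group sample mean and scaled by
the pooled SD; sex is centred at the placebo-group sample proportion. The
placebo-reference centring is essential, not cosmetic: it makes the fitted
intercept the *confounder-adjusted placebo-group mean*, which is the
quantity the intercept method back-transforms. With raw covariate coding
the intercept would be the adjusted mean at covariate zero (age 0,
sex 0) and the back-transformed difference would target the wrong point
on the logistic curve.

**Beta-regression fitting and convergence accounting.** Fitting uses
Newton–Raphson on the observed Hessian (via `statsmodels`' beta model),
at most 200 iterations; a fit counts as converged only if the optimiser
reports convergence *and* all estimates and standard errors are finite.
Newton with the observed Hessian is deliberately chosen over gradient-only
quasi-Newton: from logit-OLS starting values the Newton step is unstable
exactly where the likelihood surface is ill-conditioned — group means near
the 0/1 boundary — reproducing the practical behaviour of reference
beta-regression implementations, whereas a rescaled BFGS converges even at
a mean of 0.01 and would mask the boundary pathology the convergence study
measures. Convergence rate = converged / attempted fits per grid cell;
failures are recorded rows, never dropped.

## The bias study and its deviation measure

For each grid cell (β0, ΔBeta, c) and replicate, a fresh cohort is
simulated and each method fitted. The reference for **percent deviation**
is the *treatment-attributable* ΔBeta,

    target(c) = m_to_beta(β0_M + (1 − c)·ΔM_total) − m_to_beta(β0_M),

which equals the predefined ΔBeta when c = 0; a second column reports the
deviation against the predefined ΔBeta unconditionally. Deviations are
signed, (estimate − target)/target × 100 by default; because the
confounders act in the same direction as the treatment, the raw difference
*over*states the treatment effect and the deviation direction flips with
the convention, so `sign_convention` is an explicit parameter rather than
an implicit choice. Summaries report per-cell mean, SD, Monte-Carlo
standard error of the mean, and quantiles.

Findings at desk scale (reproduced by `analysis/03_bias_study.py` and the
acceptance tests): the intercept method is centred on its target in every
cell (deviations within Monte-Carlo noise); the raw difference is off by
roughly c/(1 − c) — about 7–16% at c = 0.10 and 19–37% at c = 0.20,
growing monotonically with c in every cell.

**A second-order caveat the simulations expose.** Even at c = 0 the raw
Beta difference is not exactly unbiased: each sample's Beta-value is the
logistic transform of a noisy M-value, so the group mean acquires a
curvature (Jensen) term ≈ ½σ²·f″(m) that does not cancel between groups.
At the default σ = 0.5 this amounts to a systematic 1–3% relative
deviation (sign depending on where the baseline sits on the logistic
curve), clearly resolvable at 200 replicates; it scales with σ² and is
negligible for low-noise probes. The intercept method is immune at order
1/n because the curvature acts on coefficient estimates whose variance is
σ²/n, not σ². This is a genuine property of reporting back-transformed
means, not a simulation artefact.

## Numerical choices

- Beta-values are clamped to [1e−6, 1 − 1e−6] before any logit
  (configurable); Eq-1-style values never reach 1, file values can.
  Values outside [0, 1] are rejected, not clamped — they indicate a unit
  error, not boundary methylation.
- `m_to_beta` evaluates through the logistic function, so large |M| never
  overflows and results stay strictly inside (0, 1).
- Round-trip accuracy is < 1e−12 across the clamped domain. Antisymmetry
  `beta_to_m(1 − b) = −beta_to_m(b)` holds to 1e−12 away from the
  boundary; within the last decade before 0/1 the *representation* of the
  complement 1 − b itself limits any implementation to ≈ eps/(1 − b)
  relative accuracy (≈ 4e−11 at b = 1e−6).
- The envelope is computed for |ΔM|; the relationship is symmetric in the
  sign. Permutation ΔBeta values are differences of back-transformed group
  M means, which by construction satisfy |ΔBeta| ≤ delta_beta_max(|ΔM|);
  the consistency check `envelope_violations` asserts this across modules.
- Replicate streams derive from a single `SeedSequence` spawn tree, so
  studies are bit-reproducible for a given seed and cell layout.

## Known limitations

- Beta regression models constant precision; real CpG sites show
  mean–precision coupling.
- The confounder mechanism is linear and additive on the M scale with two
  covariates; interactions, nonlinear age effects and unmeasured
  confounding are out of scope.
- p-values are unmoderated OLS/Wald; rankings on small cohorts would
  differ from variance-moderated pipelines even though estimates agree.
- The permutation study uses disjoint random groups within a replicate
  (a two-group comparison); other resampling conventions would change the
  null spread quantitatively but not the envelope containment.
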