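# Methods

## Problem setting

Cardiorespiratory fitness is measured by exercise testing in only a fraction
of biobank participants, so its GWAS yields few genome-wide significant
variants and a weak genetic instrument.  Resting heart rate is measured in
nearly everyone, is strongly genetically correlated with fitness, and its
GWAS is an order of magnitude better powered.  The package's central
procedure *triangulates* the two: resting-heart-rate hits whose effects are
consistent with the fitness GWAS are co-opted into an enhanced fitness
instrument, which is validated in an independent cohort before being used in
two-sample MR against disease outcomes.

## Harmonisation

Exposure and outcome effects are aligned per variant: swapped allele labels
negate the outcome beta and mirror its frequency; non-palindromic variants
reported on the opposite strand are matched through base complements.
Palindromic variants (A/T, C/G) cannot be strand-resolved from labels, so
they are dropped when the exposure effect-allele frequency lies in
(0.42, 0.58) (or is missing) and otherwise aligned by minor-allele side.
When a variant is absent from the outcome GWAS, the highest-LD available
proxy (r² > 0.8 and, when recorded, D′ > 0.8; smallest outcome p among
candidates) stands in, oriented by frequency concordance; proxies whose
frequency is uninformative (either frequency missing or inside the
palindromic band) are dropped rather than guessed.  Finally both effects are
oriented so every retained exposure beta is positive; the transformation is
idempotent and preserves |β| and σ exactly.

Tie-breaking is deterministic throughout: clumping visits variants by
ascending p, then smaller position, then lexicographic id, and a retained
variant suppresses same-chromosome variants at distance ≤ the window (1 Mb
default); proxy ties at equal p go to higher r², then lexicographic id.

## Estimators

* **IVW** — with ratio estimates r_j and first-order weights
  w_j = (σ_Yj/|β̂_Xj|)⁻², β̂ = Σw_j r_j/Σw_j.  The random-effects flavour is
  multiplicative: the fixed standard error (Σw)^(−1/2) is inflated by
  √(Q/(L−1)), floored at 1.  A single variant degenerates to the Wald ratio.
* **Cochran's Q** — Q = Σ w_j (r_j − β̂)², referred to χ²_{L−1}; the
  per-variant contributions sum to Q exactly.
* **Radial outlier filtering** — the radial regression (r_j√w_j on √w_j
  through the origin) reproduces the IVW slope; variants with Q_j
  significant at α (default 0.05, χ²₁) are removed and the model refit,
  until no new outliers or 10 passes.  When a gross outlier drags the slope
  so far that *every* variant appears heterogeneous, only the largest
  contributor is removed in that pass — without this guard a single planted
  outlier can swamp the fit and empty the instrument.  Modified
  second-order weights are available behind the `weights="second"` flag.
* **MR-Egger** — weighted regression (weights σ_Y⁻²) of β̂_Y on β̂_X with a
  free intercept, valid only in the exposure-increasing orientation; the
  standard errors carry a multiplicative overdispersion factor floored at 1.
  Constraining the intercept to zero reproduces fixed-effect IVW, which the
  tests use as a cross-check.
* **Weighted median** — ratio interpolated at 0.5 of standardised cumulative
  weight; the penalised variant multiplies weights by min(1, 20·p_j) with
  p_j the χ²₁ tail of Q_j.  Standard errors come from a seeded parametric
  bootstrap (1000 draws by default) redrawing both effect estimates from
  their reported standard errors.
* **Steiger filtering** — explained variance approximated per variant by
  z²/(z² + n); variants explaining more outcome than exposure variance are
  removed.  For binary outcomes the same approximation is applied with the
  total case+control count, a documented simplification.
* **MR-PRESSO** — observed weighted residual sum of squares about
  leave-one-out IVW fits, compared against a parametric bootstrap null
  (effects redrawn around the leave-one-out fitted values); the global p is
  the empirical upper tail with the (1+k)/(1+n) correction, per-variant
  outliers are Bonferroni-flagged at α/L, and the distortion is reported as
  the relative difference between the estimates before and after removal
  (no formal distortion test).
* **Multivariable MR** — weighted regression of β̂_Y on the exposure and
  mediator effect columns without intercept (weights σ_Y⁻²); the exposure
  coefficient is its direct effect.  An all-zero mediator column carries no
  adjustment and is dropped (coefficient 0) rather than failing the rank
  check; genuinely collinear designs raise an error naming the columns.
  Mediation is the difference method on the log-odds scale,
  100·(total − direct)/total, computed against the univariate
  random-effects IVW on the same variants; the raw value is kept alongside
  a [0, 100]-truncated value for reporting.
* All p-values are two-sided normal except heterogeneity (χ² upper tail).

## Instrument construction and validation

Candidate instruments: I1 = the exposure GWAS's independent significant
variants; I2 = proxy-trait hits harmonised against the exposure GWAS (proxy
trait in the exposure role) and kept by the radial filter *and* a
sign-consistency requirement (individual ratio agreeing with the pooled
radial slope) — both criteria are separately switchable since either reading
of "consistent effect" is defensible; I3 = the members of I2 with nominal
exposure significance (p < 0.05); I4 = the union of I1 and I3 in which, for
any cross pair with LD r² > 0.01, the I1 member is kept — proxy members are
considered greedily in ascending exposure p (ties by position then id), which
fixes the ordering the priority rule leaves open.  All weights are
exposure-GWAS betas in the exposure-increasing orientation.

Validation computes the weighted genetic risk score S_i = Σ_j w_j g_ij
(dosages oriented to the instrument's effect allele, missing entries
mean-imputed with 2·EAF, >20% absent variants aborting), then the
incremental R² of the score over a covariate-only linear model, and
phenotype means across ten equal-count score deciles (stable tie order).
The instrument with the largest R² wins; ties break to smaller p, then fewer
members.  Association scans standardise the score so betas are per score-SD
and flag traits at the Bonferroni threshold 0.05/n_tests.  One-sample MR is
the two-stage ratio — logistic outcome-on-score over linear
exposure-on-score coefficients — with a delta-method standard error ignoring
the cross-stage covariance and a first-stage F < 10 guard; this is an
approximation to full two-stage estimation, documented as such.

## Synthetic-data generator

The generator emulates the joint structure the analysis assumes, not any
particular cohort:

* **Architecture** — m variants with MAF ~ U(0.05, 0.5); standardised-scale
  effects rescaled so Σ2p(1−p)β² equals the target heritability *exactly*
  (exposure default 0.127; proxy default 0.20).  Shared-variant effect pairs
  are bivariate normal with correlation r_g/√(1 − f) where f is the
  proxy-only variant fraction, so the overall effect correlation targets r_g
  (default −0.68); an infeasible combination raises.  Outcome effects are
  θ·β_X plus an optional pleiotropy term (balanced: mean 0; directional:
  mean 0.01 *aligned to each variant's exposure-increasing allele*, since a
  mean fixed in an arbitrary allele frame cancels in ratio space); mediator
  effects are a·β_X plus a mediator-specific component with its own exact
  heritability.
* **Summary statistics** — β̂ ~ N(β, se²) with se = 1/√(n·2p(1−p)) for
  standardised continuous traits; the binary outcome uses the log-odds
  analogue with effective n = 4/(1/cases + 1/controls).  Defaults mirror the
  motivating setting: n ≈ 69k (exposure), ≈ 453k (proxy), 55,005 cases /
  400,308 controls (outcome), 150k (mediators).
* **Cohort** — dosages Binomial(2, MAF); the exposure adds small age/sex
  covariate effects and environmental noise sized for unit variance; the
  binary outcome is Bernoulli under a logistic model with the intercept
  calibrated by root-finding so the expected case fraction is met.
* **Effect-size distribution** — the estimator-benchmark scenarios (null,
  causal, balanced, directional, mediation; L = 50, θ = −0.017) draw signed
  effect magnitudes uniformly in 0.5–1.5× the mean through a Gaussian
  copula, so every variant is a usable instrument (mean single-variant
  F ≈ 175, minimum ≈ 40).  This isolates estimator calibration from
  weak-instrument regression dilution, which is what a real analysis's
  significance-selected hit list also does.  The triangulation scenario
  (m = 300, proxy-only fraction 0.3, cohort n = 10,000) keeps the normal
  architecture, because its selection and filtering steps are exactly what
  act on a weak tail.
* **LD** — linkage equilibrium by default; an optional block-diagonal
  reference (exchangeable r² within consecutive blocks) exercises proxy
  lookup and the union rule.  Cohort genotypes are always drawn
  independently, so LD affects only summary-level operations — a known
  limitation.
* A single seed drives everything through a splittable seed sequence;
  identical config + seed reproduce outputs byte-for-byte.

What passing tests show — and do not.  The generator draws independent
variants with exact heritabilities, Gaussian noise at the stated sample
sizes and clean binary case/control sampling.  Real data add realistic LD,
assortative structure, population stratification, selection into cohorts and
non-Gaussian phenotypes; calibration demonstrated here does not certify
behaviour under those violations.

## Monte-Carlo scales and numerical choices

The simulation-based checks use 500 replicates (coverage, Egger calibration,
directional-pleiotropy bias comparison, mediation recovery), 200 (radial
outlier recovery) and 100 seeded cohorts of n = 10,000 (triangulation R²
comparison) — sizes at which each check resolves its target comfortably.
"Within Monte-Carlo error" is tested as |mean − truth| ≤ 3·SEM; the mediated
percentage is summarised as the ratio of replicate means (with a
delta-method SEM) because the per-replicate ratio has a noisy denominator
and heavy tails.  Degenerate inputs fail loudly rather than silently:
zero exposure effects, non-positive standard errors, rank-deficient MVMR
designs, zero-variance scores and weak first stages all raise typed errors.

## Known limitations

No correlated-instrument (generalised) IVW, no SIMEX-corrected Egger, no
mode-based or contamination-mixture estimators; indels, multi-allelic
variants and genome-build liftover are out of scope.  Steiger filtering for
binary outcomes uses the continuous-trait variance approximation.  The
one-sample MR ratio ignores the covariance between its two stages.
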