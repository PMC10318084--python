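# fitmr

Proxy-trait triangulated genetic instruments and summary-statistics Mendelian
randomisation (MR), motivated by the problem of estimating the causal effect
of cardiorespiratory fitness — an exposure whose GWAS is under-powered because
exercise-test data exist for only a subsample of any biobank — on type 2
diabetes and related metabolic traits.

The package is for statistical geneticists and epidemiologists who work with
GWAS summary statistics.  It implements:

* **Summary-statistics plumbing** — reading/validating GWAS tables with
  configurable column dialects, distance-based clumping, high-LD proxy
  lookup, and harmonisation of exposure/outcome pairs to the
  exposure-increasing allele (`fitmr.sumstats`).
* **Instrument triangulation** — enlarging a weak exposure instrument with
  variants from a genetically correlated, well-powered proxy trait (resting
  heart rate, genetic correlation ≈ −0.68 with fitness), filtered for
  consistency with the exposure by radial MR, and validated by the variance
  each candidate instrument explains in an independent cohort
  (`fitmr.triangulate`).
* **MR estimators and diagnostics** — Wald ratio, fixed/multiplicative-random
  IVW, Cochran's Q with per-variant decomposition, MR-Egger, (penalised)
  weighted median, iterative radial outlier filtering, Steiger directionality
  filtering, MR-PRESSO, multivariable MR, mediation proportions and
  log-odds → odds-ratio / per-SD transformations (`fitmr.mr`).
* **Individual-level scores** — weighted genetic risk scores, incremental
  variance explained, decile contrasts, Bonferroni-controlled association
  scans and one-sample MR (`fitmr.grs`).
* **A synthetic-data generator** reproducing the statistical structure the
  analysis assumes (two correlated traits, realistic GWAS noise at stated
  sample sizes, pleiotropy regimes, mediators, a validation cohort)
  (`fitmr.simulate`), and a config-driven pipeline with CLI
  (`fitmr.pipeline`, `fitmr` console command).

## The statistics in brief

For harmonised per-variant effects (β̂_Xj, σ_Xj) on the exposure and
(β̂_Yj, σ_Yj) on the outcome, the Wald ratio is r_j = β̂_Yj/β̂_Xj with
first-order weight w_j = (σ_Yj/|β̂_Xj|)⁻².  The IVW estimate is
β̂ = Σw_j r_j / Σw_j; its radial reformulation regresses r_j√w_j on √w_j
through the origin, giving per-variant heterogeneity contributions
Q_j = w_j (r_j − β̂)² (χ²₁), whose sum is Cochran's Q (χ²_{L−1}).  Variants
with significant Q_j are pleiotropy suspects and are removed iteratively.
MR-Egger adds a free intercept (directional-pleiotropy test); the weighted
median interpolates the ratio at 50% of standardised cumulative weight;
multivariable MR regresses β̂_Y jointly on exposure and mediator effects
(weights σ_Y⁻²) so the exposure coefficient is its direct effect, and the
mediated share is 100·(total − direct)/total.

## Worked example

Build the four candidate instruments on a synthetic 300-variant shared
architecture (exposure heritability 0.127, proxy-trait genetic correlation
−0.68) and validate them in a 10,000-person cohort:

```bash
fitmr run --scenario triangulation --seed 7 --out-dir demo
cut -f1-4 demo/validation.tsv
```

```
label   r_squared               p                       n_members
I1      0.11060356836699436     1.1923696839816704e-260 83
I2      0.01694224485110507     1.4283504350344602e-39  65
I3      0.015651986586424083    1.1493039844700443e-36  40
I4      0.11715168277479526     5.801536712629382e-277  114
```

I1 holds the exposure GWAS's own significant hits; I2 the proxy-trait hits
passing the radial consistency filter; I3 its nominally exposure-associated
subset; I4 the LD-pruned union of I1 and I3.  The combined instrument I4
explains the most phenotypic variance and is selected for the MR stage, whose
tidy per-method results (IVW, Egger, weighted medians, before/after radial
filtering, with Q statistics) land in `demo/mr_results.tsv`.

Converting a log-odds MR estimate of −0.0284 (se 0.0165) for an exposure on a
binary outcome to an odds-ratio scale:

```python
>>> import fitmr
>>> fitmr.or_from_logodds(-0.0284, 0.0165)
OddsRatio(odds_ratio=0.9719994892352246, ci_low=0.9410684448554796,
          ci_high=1.003947175402984, p=0.08521233908614347)
```

i.e. OR 0.97 (95% CI 0.94–1.00) per unit of exposure: a ~3% lower odds per
unit, not conventionally significant before heterogeneity filtering.

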