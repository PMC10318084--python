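"""Individual-level genetic-risk-score operations.

A weighted genetic risk score (GRS) sums, for each individual, the number of
exposure-increasing alleles at each instrument variant weighted by the
variant's per-allele effect on the exposure.  On a cohort with measured
phenotypes the score supports instrument validation (incremental variance
explained), decile contrasts, phenome-style association scans with
Bonferroni control, and one-sample Mendelian randomisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mr import MrError, MrEstimate, _estimate
from .sumstats import log_drop

logger = logging.getLogger("fitmr")


class GrsError(ValueError):
    """Cohort or score input unsuitable for the requested operation."""


@dataclass
class CohortData:
    """Individual-level dosages, phenotypes and covariates.

    ``dosages`` is individuals x variants with entries in [0, 2] (fractional
    imputed dosages allowed, NaN for missing); ``variant_meta`` gives, per
    dosage column, the allele the dosage counts (``effect_allele``), the
    other allele, and optionally ``eaf`` used for mean imputation.
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame
    variant_meta: pd.DataFrame  # columns: variant_id, effect_allele, other_allele[, eaf]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.dosages) != len(self.phenotypes):
            raise GrsError("dosage and phenotype row counts differ")
        if self.covariates is not None and len(self.covariates) != len(self.dosages):
            raise GrsError("covariate row count differs from dosages")
        meta_ids = list(self.variant_meta["variant_id"])
        if meta_ids != list(self.dosages.columns):
            raise GrsError("variant_meta rows must align with dosage columns")
        vals = self.dosages.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise GrsError("dosages must lie in [0, 2]")


def compute_grs(cohort: CohortData, instrument) -> np.ndarray:
    """Weighted genetic risk score S_i = sum_j w_j g_ij.

    Dosages are oriented to each instrument member's effect allele (a dosage
    stored for the other allele becomes 2 - g).  Missing dosage entries are
    mean-imputed with 2*eaf when the frequency is known, else with the column
    mean.  More than 20% of instrument variants absent from the cohort aborts.
    """
    meta = cohort.variant_meta.set_index("variant_id")
    members = instrument.members
    absent = [m.variant_id for m in members if m.variant_id not in meta.index]
    if len(absent) > 0.2 * len(members):
        raise GrsError(f"{len(absent)}/{len(members)} instrument variants "
                       f"missing from cohort (>20%)")
    for vid in absent:
        log_drop("grs", vid, "absent_from_cohort")
    score = np.zeros(len(cohort.dosages))
    for m in members:
        if m.variant_id in absent:
            continue
        g = cohort.dosages[m.variant_id].to_numpy(float).copy()
        row = meta.loc[m.variant_id]
        if row["effect_allele"] == m.effect_allele:
            pass
        elif row["other_allele"] == m.effect_allele:
            g = 2.0 - g
        else:
            log_drop("grs", m.variant_id, "allele_mismatch")
            continue
        nan = ~np.isfinite(g)
        if nan.any():
            eaf = row.get("eaf", np.nan)
            fill = 2.0 * eaf if np.isfinite(eaf) else np.nanmean(g)
            g[nan] = fill
        score += m.weight * g
    return score


def variance_explained(scores: np.ndarray, phenotype: np.ndarray,
                       covariates: pd.DataFrame | np.ndarray | None = None
                       ) -> tuple[float, float]:
    """Incremental R^2 of the score over a covariate-only linear model.

    Returns (R^2 gained by adding the score, p-value of its coefficient).
    """
    scores = np.asarray(scores, float)
    phenotype = np.asarray(phenotype, float)
    if len(scores) < 30:
        raise GrsError("need at least 30 individuals")
    if np.std(scores) == 0:
        raise GrsError("score has zero variance")
    if covariates is None:
        base = np.ones((len(scores), 1))
    else:
        cov = np.asarray(covariates, float)
        base = np.column_stack([np.ones(len(scores)), cov])
    fit0 = sm.OLS(phenotype, base).fit()
    fit1 = sm.OLS(phenotype, np.column_stack([base, scores])).fit()
    return float(fit1.rsquared - fit0.rsquared), float(fit1.pvalues[-1])


def decile_contrast(scores: np.ndarray, phenotype: np.ndarray) -> float:
    """Mean phenotype difference between top and bottom score deciles.

    Deciles are equal-count by score rank with stable tie ordering.
    """
    scores = np.asarray(scores, float)
    phenotype = np.asarray(phenotype, float)
    n = len(scores)
    if n < 20:
        raise GrsError("need at least 20 individuals for deciles")
    order = np.argsort(scores, kind="stable")
    deciles = np.minimum(np.arange(n) * 10 // n, 9)
    top = phenotype[order[deciles == 9]]
    bottom = phenotype[order[deciles == 0]]
    return float(top.mean() - bottom.mean())


def decile_means(scores: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Mean phenotype within each of 10 equal-count score deciles (ascending)."""
    scores = np.asarray(scores, float)
    phenotype = np.asarray(phenotype, float)
    n = len(scores)
    if n < 20:
        raise GrsError("need at least 20 individuals for deciles")
    order = np.argsort(scores, kind="stable")
    deciles = np.minimum(np.arange(n) * 10 // n, 9)
    return np.array([phenotype[order[deciles == d]].mean() for d in range(10)])


def association_scan(scores: np.ndarray, traits: pd.DataFrame,
                     covariates: pd.DataFrame | np.ndarray | None = None,
                     n_tests: int | None = None) -> pd.DataFrame:
    """Regress each trait on the standardised score; Bonferroni-flag results.

    The score is standardised to mean 0, SD 1, so betas are per SD of score.
    ``n_tests`` defaults to the number of traits supplied and may be larger
    (when the scan is part of a wider family); it cannot be smaller.
    Per-trait missingness is handled by complete-case analysis.
    Returns a DataFrame (trait, beta, se, p, significant) where
    significant <=> p < 0.05/n_tests.
    """
    scores = np.asarray(scores, float)
    if np.std(scores) == 0:
        raise GrsError("score has zero variance")
    if n_tests is None:
        n_tests = traits.shape[1]
    if n_tests < traits.shape[1]:
        raise GrsError(f"n_tests ({n_tests}) < number of traits ({traits.shape[1]})")
    z = (scores - scores.mean()) / scores.std()
    threshold = 0.05 / n_tests
    if covariates is None:
        cov = np.empty((len(z), 0))
    else:
        cov = np.asarray(covariates, float)
    rows = []
    for trait in traits.columns:
        y = traits[trait].to_numpy(float)
        ok = np.isfinite(y)
        X = np.column_stack([np.ones(ok.sum()), z[ok], cov[ok]])
        fit = sm.OLS(y[ok], X).fit()
        rows.append({"trait": trait, "beta": float(fit.params[1]),
                     "se": float(fit.bse[1]), "p": float(fit.pvalues[1]),
                     "significant": bool(fit.pvalues[1] < threshold)})
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    out.attrs["n_tests"] = n_tests
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha/n_tests."""
    if n_tests < 1:
        raise GrsError("n_tests must be positive")
    return alpha / n_tests


def one_sample_mr(cohort: CohortData, instrument, outcome: str,
                  exposure: str) -> MrEstimate:
    """One-sample MR via the two-stage ratio on a standardised GRS.

    The logistic coefficient of the binary outcome on the standardised score
    is divided by the linear coefficient of the exposure on the same score;
    the standard error follows by the delta method (stage covariance
    ignored).  A first-stage F below 10 raises a weak-instrument error.
    """
    score = compute_grs(cohort, instrument)
    if np.std(score) == 0:
        raise GrsError("score has zero variance")
    z = (score - score.mean()) / score.std()
    x = cohort.phenotypes[exposure].to_numpy(float)
    y = cohort.phenotypes[outcome].to_numpy(float)
    uniq = set(np.unique(y[np.isfinite(y)]))
    if not uniq <= {0.0, 1.0}:
        raise GrsError(f"outcome {outcome!r} is not binary 0/1")
    X1 = sm.add_constant(z)
    first = sm.OLS(x, X1).fit()
    den, den_se = float(first.params[1]), float(first.bse[1])
    f_stat = (den / den_se) ** 2
    if f_stat < 10:
        raise GrsError(f"weak instrument: first-stage F = {f_stat:.2f} < 10")
    second = sm.GLM(y, X1, family=sm.families.Binomial()).fit()
    num, num_se = float(second.params[1]), float(second.bse[1])
    beta = num / den
    se = np.sqrt(num_se**2 / den**2 + num**2 * den_se**2 / den**4)
    return _estimate("one_sample_mr", beta, se, len(instrument.members))
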