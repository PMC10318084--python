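"""Summary-statistics Mendelian randomisation estimators and diagnostics.

All estimators operate on a :class:`~fitmr.sumstats.HarmonisedSet` in which
every variant's effects are aligned to the exposure-increasing allele.  The
per-variant (Wald) ratio estimate is r_j = beta_out_j / beta_exp_j with
first-order weight w_j = (se_out_j / |beta_exp_j|)^-2; the inverse-variance
weighted (IVW) estimate is the w-weighted mean of the r_j.  Heterogeneity of
the ratios (Cochran's Q) is the diagnostic for horizontal pleiotropy, and the
radial reformulation — regressing r_j * sqrt(w_j) on sqrt(w_j) through the
origin — provides per-variant Q contributions used for outlier removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .sumstats import HarmonisedSet, log_drop

logger = logging.getLogger("fitmr")

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


class MrError(ValueError):
    """Input unsuitable for the requested estimator."""


@dataclass
class MrEstimate:
    """A causal-effect estimate with its uncertainty.

    ``beta`` is on the exposure-unit scale of the harmonised set (log-odds per
    exposure unit for a binary outcome).  For MR-Egger the pleiotropy
    intercept and its test are carried alongside the slope.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


@dataclass
class HeterogeneityStats:
    """Cochran's Q with its per-variant decomposition (sum(q) == Q)."""

    Q: float
    df: int
    p: float
    q_contributions: np.ndarray
    variant_ids: list[str] = field(default_factory=list)


@dataclass
class MvmrResult:
    """Direct effects from multivariable MR, plus the implied mediation split."""

    exposures: list[str]          # first entry is the primary exposure
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n_snps: int
    total_beta: float             # univariate IVW total effect of the exposure
    mediation_percent: float      # 100 * (total - direct) / total, untruncated
    mediation_percent_reported: float  # truncated to [0, 100]


class PressoResult(NamedTuple):
    global_p: float
    outliers: list[str]
    estimate_before: MrEstimate
    estimate_after: MrEstimate
    distortion: float  # relative difference between before/after estimates


def _normal_p(z: float | np.ndarray) -> float | np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def _estimate(method: str, beta: float, se: float, n_snps: int, **kw) -> MrEstimate:
    return MrEstimate(method=method, beta=float(beta), se=float(se),
                      ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
                      p=float(_normal_p(beta / se)) if se > 0 else 1.0,
                      n_snps=n_snps, **kw)


def _ratios(h: HarmonisedSet, weights: str = "first"
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant ratio estimates and inverse-variance weights."""
    bx = h.df["beta_exp"].to_numpy(float)
    sx = h.df["se_exp"].to_numpy(float)
    by = h.df["beta_out"].to_numpy(float)
    sy = h.df["se_out"].to_numpy(float)
    if np.any(bx == 0):
        raise MrError("zero exposure effect; cannot form ratio estimates")
    r = by / bx
    if weights == "first":
        var = (sy / np.abs(bx)) ** 2
    elif weights == "second":  # modified second-order ratio variance
        var = sy**2 / bx**2 + (by**2 * sx**2) / bx**4
    else:
        raise MrError(f"unknown weight scheme {weights!r}")
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        raise MrError("degenerate (zero or non-finite) ratio variances")
    return r, 1.0 / var, bx, by


# ---------------------------------------------------------------------------
# basic estimators
# ---------------------------------------------------------------------------

def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float
               ) -> MrEstimate:
    """Single-variant causal estimate: outcome effect over exposure effect.

    The first-order standard error se_out/|beta_exp| ignores exposure-side
    noise, which is negligible for strong instruments.
    """
    if beta_exp == 0:
        raise MrError("wald_ratio undefined for zero exposure effect")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _estimate("wald_ratio", beta, se, 1)


def ivw(h: HarmonisedSet, model: str = "random") -> MrEstimate:
    """Inverse-variance weighted estimate over the set's Wald ratios.

    ``model="fixed"`` uses se = (sum w)^-1/2; ``"random"`` is the
    multiplicative random-effects flavour, inflating the fixed se by
    sqrt(Q/(L-1)) floored at 1.  A single-variant set degenerates to the
    Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise MrError(f"unknown IVW model {model!r}")
    if len(h) < 2:
        if len(h) == 0:
            raise MrError("empty harmonised set")
        row = h.df.iloc[0]
        est = wald_ratio(row["beta_exp"], row["se_exp"],
                         row["beta_out"], row["se_out"])
        return replace(est, method=f"ivw_{model}")
    r, w, _, _ = _ratios(h)
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if model == "random":
        q = float(np.sum(w * (r - beta) ** 2))
        se = se_fixed * max(1.0, np.sqrt(q / (len(r) - 1)))
    else:
        se = se_fixed
    return _estimate(f"ivw_{model}", beta, se, len(r))


def cochran_q(h: HarmonisedSet, beta: float | None = None) -> HeterogeneityStats:
    """Cochran's Q of the ratio estimates about a pooled effect.

    With the default ``beta=None`` the fixed-effect IVW estimate is used, so
    Q has L-1 degrees of freedom.
    """
    if len(h) < 2:
        raise MrError("Cochran's Q needs at least 2 variants")
    r, w, _, _ = _ratios(h)
    if beta is None:
        beta = float(np.sum(w * r) / np.sum(w))
    qj = w * (r - beta) ** 2
    q = float(np.sum(qj))
    dof = len(r) - 1
    return HeterogeneityStats(Q=q, df=dof, p=float(stats.chi2.sf(q, dof)),
                              q_contributions=qj,
                              variant_ids=list(h.df["variant_id"]))


def egger(h: HarmonisedSet, constrain_intercept: bool = False) -> MrEstimate:
    """MR-Egger: weighted regression of outcome on exposure effects with an
    unconstrained intercept.

    The slope is the causal estimate, consistent under the InSIDE assumption;
    a non-zero intercept signals unbalanced (directional) horizontal
    pleiotropy.  Weights are 1/se_out^2; standard errors use a multiplicative
    overdispersion factor floored at 1.  ``constrain_intercept=True`` fixes
    the intercept at zero, which reproduces fixed-effect IVW.
    """
    if len(h) < 3 and not constrain_intercept:
        raise MrError("MR-Egger needs at least 3 variants")
    bx = h.df["beta_exp"].to_numpy(float)
    by = h.df["beta_out"].to_numpy(float)
    w = h.df["se_out"].to_numpy(float) ** -2.0
    if np.any(bx <= 0):
        raise MrError("egger requires exposure-increasing orientation (beta_exp > 0)")
    X = bx[:, None] if constrain_intercept else np.column_stack([np.ones_like(bx), bx])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], by * sw, rcond=None)
    resid = by - X @ coef
    k = X.shape[1]
    phi = max(1.0, float(np.sum(w * resid**2) / max(len(bx) - k, 1)))
    cov = phi * np.linalg.inv((X * w[:, None]).T @ X)
    if constrain_intercept:
        return _estimate("egger_constrained", coef[0], np.sqrt(cov[0, 0]), len(bx))
    slope_se = float(np.sqrt(cov[1, 1]))
    int_se = float(np.sqrt(cov[0, 0]))
    return _estimate(
        "egger", coef[1], slope_se, len(bx),
        intercept=float(coef[0]), intercept_se=int_se,
        intercept_p=float(_normal_p(coef[0] / int_se)))


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    Orders the ratios, forms standardised cumulative weights
    s_j = (cumsum(w)_j - w_j/2) / sum(w), and linearly interpolates the
    ratio at s = 0.5.
    """
    order = np.argsort(r, kind="stable")
    r, w = r[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(h: HarmonisedSet, penalised: bool = False,
                    n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Weighted-median causal estimate, robust to <50% invalid weight.

    The penalised variant down-weights heterogeneous variants by
    min(1, 20 * p_j), where p_j is the chi-square(1) p-value of that
    variant's Q contribution about the IVW estimate.  Standard errors come
    from a seeded parametric bootstrap (effects redrawn from their reported
    standard errors).
    """
    if len(h) < 3:
        raise MrError("weighted median needs at least 3 variants")
    r, w, _, _ = _ratios(h)

    def penalise(r_, w_):
        beta_ivw = np.sum(w_ * r_) / np.sum(w_)
        pj = stats.chi2.sf(w_ * (r_ - beta_ivw) ** 2, 1)
        return w_ * np.minimum(1.0, 20.0 * pj)

    beta = _weighted_median(r, penalise(r, w) if penalised else w)

    rng = np.random.default_rng(seed)
    bx = h.df["beta_exp"].to_numpy(float)
    sx = h.df["se_exp"].to_numpy(float)
    by = h.df["beta_out"].to_numpy(float)
    sy = h.df["se_out"].to_numpy(float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0
        r_b = by_b[ok] / bx_b[ok]
        w_b = (np.abs(bx_b[ok]) / sy[ok]) ** 2
        boots[b] = _weighted_median(r_b, penalise(r_b, w_b) if penalised else w_b)
    se = float(np.std(boots, ddof=1))
    name = "penalised_weighted_median" if penalised else "weighted_median"
    return _estimate(name, beta, se, len(r))


# ---------------------------------------------------------------------------
# radial filtering
# ---------------------------------------------------------------------------

def radial_fit(h: HarmonisedSet, weights: str = "first"
               ) -> tuple[float, float, HeterogeneityStats]:
    """Fit the radial IVW model and decompose heterogeneity per variant.

    Regressing r_j*sqrt(w_j) on sqrt(w_j) through the origin yields the IVW
    slope; the squared residuals are the per-variant Q contributions
    Q_j = w_j (r_j - beta)^2, each referred to chi-square(1).
    """
    if len(h) < 3:
        raise MrError("radial fit needs at least 3 variants")
    r, w, _, _ = _ratios(h, weights=weights)
    sw = np.sqrt(w)
    beta = float(np.sum(sw * (r * sw)) / np.sum(w))  # origin-constrained slope
    qj = w * (r - beta) ** 2
    q = float(np.sum(qj))
    dof = len(r) - 1
    het = HeterogeneityStats(Q=q, df=dof, p=float(stats.chi2.sf(q, dof)),
                             q_contributions=qj,
                             variant_ids=list(h.df["variant_id"]))
    se = float(np.sum(w) ** -0.5)
    return beta, se, het


def radial_outlier_filter(h: HarmonisedSet, alpha: float = 0.05,
                          weights: str = "first", max_iter: int = 10
                          ) -> tuple[HarmonisedSet, list[str]]:
    """Iteratively remove variants with significant radial Q contributions.

    At each pass the radial model is refit and variants whose Q_j exceeds the
    chi-square(1) upper-alpha quantile are removed, until no new outliers
    emerge or ``max_iter`` passes.  When a single gross outlier drags the
    slope far enough that every variant appears heterogeneous (swamping),
    only the largest contributor is removed in that pass.  A perfectly
    homogeneous set is returned unchanged.
    """
    current = h
    outliers: list[str] = []
    for _ in range(max_iter):
        if len(current) < 3:
            break
        _, _, het = radial_fit(current, weights=weights)
        pj = stats.chi2.sf(het.q_contributions, 1)
        bad = np.asarray(pj) < alpha
        if not bad.any():
            break
        if bad.all():
            worst = int(np.argmax(het.q_contributions))
            bad = np.zeros_like(bad)
            bad[worst] = True
        ids = [v for v, b in zip(het.variant_ids, bad) if b]
        for vid in ids:
            log_drop("radial", vid, "q_outlier", alpha=alpha)
        outliers.extend(ids)
        keep = [v for v in current.df["variant_id"] if v not in set(ids)]
        current = current.subset(keep)
    if len(current) == 0:
        raise MrError("radial filtering removed every variant")
    return current, outliers


# ---------------------------------------------------------------------------
# Steiger directionality filtering
# ---------------------------------------------------------------------------

def steiger_filter(h: HarmonisedSet, n_exp: float | None = None,
                   n_out: float | None = None
                   ) -> tuple[HarmonisedSet, list[str]]:
    """Drop variants that explain more outcome than exposure variance.

    Explained variance is approximated per variant as z^2/(z^2 + n) with
    z = beta/se; a variant with rho2_outcome > rho2_exposure is more plausibly
    acting on the outcome first (reverse direction) and is removed.  For a
    binary outcome the same approximation is applied with the total
    case+control count as n.
    """
    zx = h.df["beta_exp"].to_numpy(float) / h.df["se_exp"].to_numpy(float)
    zy = h.df["beta_out"].to_numpy(float) / h.df["se_out"].to_numpy(float)
    nx = np.full(len(h), n_exp) if n_exp is not None else h.df["n_exp"].to_numpy(float)
    ny = np.full(len(h), n_out) if n_out is not None else h.df["n_out"].to_numpy(float)
    if np.any(~np.isfinite(nx)) or np.any(~np.isfinite(ny)):
        raise MrError("steiger_filter requires sample sizes for every variant")
    rho2_x = zx**2 / (zx**2 + nx)
    rho2_y = zy**2 / (zy**2 + ny)
    bad = rho2_y > rho2_x
    removed = [v for v, b in zip(h.df["variant_id"], bad) if b]
    for vid in removed:
        log_drop("steiger", vid, "reverse_direction")
    kept = h.subset([v for v, b in zip(h.df["variant_id"], bad) if not b])
    return kept, removed


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def mr_presso(h: HarmonisedSet, n_sim: int = 1000, seed: int = 0,
              alpha: float = 0.05) -> PressoResult:
    """Pleiotropy residual sum of squares and outlier test.

    The observed statistic is the weighted residual sum of squares of each
    variant about the leave-one-out IVW fit; its null distribution is built
    by parametric bootstrap (``n_sim`` draws of the effect estimates from
    their standard errors around the leave-one-out fitted values).  The
    global p is the empirical upper-tail proportion; per-variant outliers are
    flagged by comparing each observed weighted residual with its simulated
    distribution at a Bonferroni-adjusted level alpha/L.  Estimates (random
    effects IVW) before and after outlier removal are reported together with
    their relative difference.
    """
    if len(h) < 4:
        raise MrError("MR-PRESSO needs at least 4 variants")
    if n_sim < 100:
        raise MrError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    r, w, bx, by = _ratios(h)
    sy = h.df["se_out"].to_numpy(float)
    sx = h.df["se_exp"].to_numpy(float)
    L = len(r)

    def loo_beta(r_, w_):
        # leave-one-out IVW slope for each variant, vectorised
        tw, twr = np.sum(w_, axis=-1, keepdims=True), np.sum(w_ * r_, axis=-1, keepdims=True)
        return (twr - w_ * r_) / (tw - w_)

    b_loo = loo_beta(r, w)
    resid2_obs = (by - b_loo * bx) ** 2 / sy**2
    rss_obs = float(np.sum(resid2_obs))

    bx_s = rng.normal(bx, sx, size=(n_sim, L))
    by_s = rng.normal(b_loo * bx, sy, size=(n_sim, L))
    ok = bx_s == 0
    if ok.any():
        bx_s[ok] = np.finfo(float).tiny
    r_s = by_s / bx_s
    w_s = (np.abs(bx_s) / sy) ** 2
    b_loo_s = loo_beta(r_s, w_s)
    resid2_s = (by_s - b_loo_s * bx_s) ** 2 / sy**2
    rss_s = np.sum(resid2_s, axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (1 + n_sim))
    pj = (1 + np.sum(resid2_s >= resid2_obs, axis=0)) / (1 + n_sim)
    out_mask = pj < alpha / L
    outliers = [v for v, b in zip(h.df["variant_id"], out_mask) if b]

    before = ivw(h, model="random")
    if outliers and L - len(outliers) >= 2:
        after = ivw(h.subset([v for v in h.df["variant_id"] if v not in set(outliers)]),
                    model="random")
    else:
        after = before
    distortion = (abs(after.beta - before.beta) / abs(before.beta)
                  if before.beta != 0 else 0.0)
    return PressoResult(global_p, outliers, before, after, float(distortion))


# ---------------------------------------------------------------------------
# multivariable MR and mediation
# ---------------------------------------------------------------------------

def mvmr(h: HarmonisedSet, which: Sequence[str] | None = None) -> MvmrResult:
    """Multivariable MR: direct effect of the exposure given mediators.

    Weighted multivariable regression (weights 1/se_out^2, no intercept) of
    the outcome effects on the exposure and mediator effect columns.  The
    coefficient on the exposure column is its direct effect; the implied
    mediation percentage compares it with the univariate random-effects IVW
    total effect on the same variants.
    """
    labels = list(which) if which is not None else list(h.mediator_labels)
    missing = [m for m in labels if f"beta_med_{m}" not in h.df.columns]
    if missing:
        raise MrError(f"mediator effects absent for: {missing}")
    cols = ["beta_exp"] + [f"beta_med_{m}" for m in labels]
    X_full = h.df[cols].to_numpy(float)
    y = h.df["beta_out"].to_numpy(float)
    w = h.df["se_out"].to_numpy(float) ** -2.0
    # a mediator with no genetic effects carries no adjustment: drop its
    # all-zero column (coefficient reported as 0) instead of failing on rank
    zero = np.all(X_full == 0, axis=0)
    if zero[0]:
        raise MrError("exposure effects are all zero")
    active = ~zero
    X = X_full[:, active]
    cols_active = [c for c, a in zip(cols, active) if a]
    L, k = X.shape
    if L < k + 1:
        raise MrError(f"need at least {k + 1} variants for {k} exposures")
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < k:
        # identify which columns are mutually collinear for the error message
        bad = []
        for j in range(k):
            others = np.delete(Xw, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(cols_active[j])
        raise MrError(f"rank-deficient design; collinear columns: {bad or cols_active}")
    coef_a, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
    resid = y - X @ coef_a
    phi = max(1.0, float(np.sum(w * resid**2) / max(L - k, 1)))
    cov = phi * np.linalg.inv(Xw.T @ Xw)
    se_a = np.sqrt(np.diag(cov))
    coef = np.zeros(len(cols))
    se = np.full(len(cols), np.nan)
    coef[active] = coef_a
    se[active] = se_a
    with np.errstate(invalid="ignore", divide="ignore"):
        p = _normal_p(np.where(np.isfinite(se), coef / se, np.nan))
    total = ivw(h, model="random").beta
    med_raw = 100.0 * (total - coef[0]) / total if total != 0 else np.nan
    return MvmrResult(
        exposures=[h.exposure_label] + labels,
        beta=coef, se=se, p=np.asarray(p), n_snps=L,
        total_beta=total,
        mediation_percent=float(med_raw),
        mediation_percent_reported=float(np.clip(med_raw, 0.0, 100.0)))


class MediationProportion(NamedTuple):
    raw: float       # 100 * (total - direct) / total, may leave [0, 100]
    reported: float  # truncated to [0, 100]


def mediation_proportion(total: MrEstimate, direct: MrEstimate) -> MediationProportion:
    """Difference-method mediation: share of the total effect not acting directly."""
    if total.beta == 0:
        raise MrError("mediation undefined for zero total effect")
    raw = 100.0 * (total.beta - direct.beta) / total.beta
    return MediationProportion(float(raw), float(np.clip(raw, 0.0, 100.0)))


# ---------------------------------------------------------------------------
# effect-size transformations
# ---------------------------------------------------------------------------

class OddsRatio(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


def or_from_logodds(beta: float, se: float) -> OddsRatio:
    """Exponentiate a log-odds estimate into an odds ratio with 95% CI."""
    if se <= 0:
        raise MrError("se must be positive")
    return OddsRatio(float(np.exp(beta)),
                     float(np.exp(beta - Z95 * se)),
                     float(np.exp(beta + Z95 * se)),
                     float(_normal_p(beta / se)) if beta != 0 else 1.0)


def per_sd_scale(estimate: MrEstimate, sd: float) -> MrEstimate:
    """Rescale a per-unit estimate to per-SD of the exposure."""
    if sd <= 0:
        raise MrError("sd must be positive")
    return _estimate(f"{estimate.method}_per_sd", estimate.beta * sd,
                     estimate.se * sd, estimate.n_snps,
                     intercept=estimate.intercept,
                     intercept_se=estimate.intercept_se,
                     intercept_p=estimate.intercept_p)
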