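"""Synthetic GWAS architecture, summary statistics and validation cohorts.

The generator emulates the statistical structure the analysis assumes: two
genetically correlated standardised continuous traits (an under-powered
exposure and a well-powered proxy), a binary outcome causally downstream of
the exposure on the log-odds scale, optional mediator traits and pleiotropy
regimes, GWAS sampling noise appropriate to stated sample sizes, and an
individual-level validation cohort.

Effect sizes are drawn on the standardised-trait scale and rescaled so the
realised SNP heritability sum(2 p (1-p) beta^2) matches the target exactly.
Shared-variant effects for the two traits are drawn from a bivariate normal
whose correlation is chosen so the overall effect-size correlation matches
the target genetic correlation after accounting for proxy-only variants.
Defaults mirror a fitness/resting-heart-rate setting: exposure heritability
0.127, genetic correlation -0.68, GWAS sizes ~69k (exposure), ~453k (proxy)
and 55,005 cases / 400,308 controls (outcome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .grs import CohortData
from .sumstats import CANONICAL_COLUMNS, LdReference, SummaryTable

logger = logging.getLogger("fitmr")

# non-palindromic allele pairs cycled across variants
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


class SimulationError(ValueError):
    """Infeasible or inconsistent simulation parameters."""


@dataclass(frozen=True)
class MediatorSpec:
    """One mediator trait on the exposure -> mediator -> outcome path.

    ``a`` is the effect of the exposure on the mediator (per exposure SD),
    ``b`` the effect of the mediator on the outcome (log-odds per mediator
    SD), and ``h2_specific`` the mediator-specific SNP heritability that
    keeps its genetic effects from being collinear with the exposure's.
    """

    label: str
    a: float
    b: float
    h2_specific: float = 0.05
    n_gwas: int = 150_000


@dataclass
class SimulationParams:
    """Genetic architecture and noise model for the synthetic generator."""

    m: int = 50                                  # variant count
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_exposure: float = 0.127
    h2_proxy: float = 0.20
    r_g: float = -0.68
    proxy_only_fraction: float = 0.3             # variants with zero exposure effect
    theta: float = -0.017                        # direct log-odds effect of exposure
    effect_distribution: str = "normal"          # normal | uniform (signed, bounded)
    pleiotropy_model: str = "none"               # none | balanced | directional
    pleiotropy_fraction: float = 0.3
    pleiotropy_mean: float = 0.01
    pleiotropy_sd: float = 0.005
    mediators: tuple[MediatorSpec, ...] = ()
    n_exposure: int = 69_416
    n_proxy: int = 452_941
    n_cases: int = 55_005
    n_controls: int = 400_308
    n_cohort: int = 10_000
    case_fraction: float = 0.07
    ld_block_size: int = 1                       # 1 => linkage equilibrium
    ld_r2_within: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2_exposure < 1 or not 0 < self.h2_proxy < 1:
            raise SimulationError("heritabilities must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not -1 <= self.r_g <= 1:
            raise SimulationError("r_g must lie in [-1, 1]")
        if not 0 <= self.proxy_only_fraction < 1:
            raise SimulationError("proxy_only_fraction must lie in [0, 1)")
        if self.pleiotropy_model not in ("none", "balanced", "directional"):
            raise SimulationError(f"unknown pleiotropy model {self.pleiotropy_model!r}")
        if self.effect_distribution not in ("normal", "uniform"):
            raise SimulationError(
                f"unknown effect distribution {self.effect_distribution!r}")
        if not 0 < self.case_fraction < 1:
            raise SimulationError("case_fraction must lie in (0, 1)")

    @property
    def theta_total(self) -> float:
        """Total log-odds effect of the exposure: direct plus mediated paths."""
        return self.theta + sum(m.a * m.b for m in self.mediators)


@dataclass
class Architecture:
    """True per-variant effects on the standardised per-allele scale."""

    maf: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    beta_exposure: np.ndarray
    beta_proxy: np.ndarray
    beta_outcome: np.ndarray
    beta_mediators: dict[str, np.ndarray] = field(default_factory=dict)
    pleiotropy: np.ndarray | None = None

    @property
    def m(self) -> int:
        return len(self.maf)

    @property
    def variant_ids(self) -> list[str]:
        return [f"rs{i + 1}" for i in range(self.m)]


def _het_var(maf: np.ndarray) -> np.ndarray:
    return 2.0 * maf * (1.0 - maf)


def _rescale_to_h2(beta: np.ndarray, maf: np.ndarray, h2: float) -> np.ndarray:
    """Rescale effects so sum(2p(1-p) beta^2) equals h2 exactly."""
    total = float(np.sum(_het_var(maf) * beta**2))
    if total == 0:
        raise SimulationError("cannot rescale all-zero effects to positive h2")
    return beta * np.sqrt(h2 / total)


def simulate_architecture(params: SimulationParams,
                          rng: np.random.Generator | None = None) -> Architecture:
    """Draw true per-variant effects for exposure, proxy, mediators, outcome."""
    rng = rng or np.random.default_rng(params.seed)
    m = params.m
    maf = rng.uniform(*params.maf_range, size=m)
    chrom = np.array([str(i % 22 + 1) for i in range(m)])
    pos = np.array([10_000_000 + (i // 22) * 5_000_000 for i in range(m)], dtype=np.int64)
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    ea = np.array([p[0] for p in pairs])
    oa = np.array([p[1] for p in pairs])

    m_po = int(round(params.proxy_only_fraction * m))
    m_sh = m - m_po
    if m_sh < 1:
        raise SimulationError("no shared variants left")
    share = 1.0 - params.proxy_only_fraction
    rho_shared = params.r_g / np.sqrt(share) if share > 0 else np.nan
    if not np.isfinite(rho_shared) or abs(rho_shared) > 1:
        raise SimulationError(
            f"infeasible r_g={params.r_g} given proxy_only_fraction="
            f"{params.proxy_only_fraction}: shared correlation would be {rho_shared:.3f}")
    cov = np.array([[1.0, rho_shared], [rho_shared, 1.0]])
    u = rng.multivariate_normal([0.0, 0.0], cov, size=m_sh)
    u_x = np.concatenate([u[:, 0], np.zeros(m_po)])
    u_p = np.concatenate([u[:, 1], rng.standard_normal(m_po)])
    if params.effect_distribution == "uniform":
        # signed magnitudes in [0.5, 1.5] through a Gaussian copula: keeps the
        # cross-trait dependence while bounding instrument strength away from
        # zero (every variant a usable instrument, as in a selected hit list)
        def to_uniform(z):
            t = 2.0 * np.abs(stats.norm.cdf(z) - 0.5)  # Uniform(0,1)
            return np.sign(z) * (0.5 + t)
        nz_x = u_x != 0
        u_x[nz_x] = to_uniform(u_x[nz_x])
        u_p = to_uniform(u_p)

    beta_x = _rescale_to_h2(u_x, maf, params.h2_exposure)
    beta_p = _rescale_to_h2(u_p, maf, params.h2_proxy)

    beta_med: dict[str, np.ndarray] = {}
    for spec in params.mediators:
        delta = _rescale_to_h2(rng.standard_normal(m), maf, spec.h2_specific)
        beta_med[spec.label] = spec.a * beta_x + delta

    pleio = np.zeros(m)
    if params.pleiotropy_model != "none":
        k = int(round(params.pleiotropy_fraction * m))
        idx = rng.choice(m, size=k, replace=False)
        mean = params.pleiotropy_mean if params.pleiotropy_model == "directional" else 0.0
        draws = rng.normal(mean, params.pleiotropy_sd, size=k)
        if params.pleiotropy_model == "directional":
            # directional means a common shift on the exposure-increasing
            # allele; align the mean with each variant's orientation
            sgn = np.sign(beta_x[idx])
            sgn[sgn == 0] = 1.0
            draws = draws * sgn
        pleio[idx] = draws

    beta_y = params.theta * beta_x + pleio
    for spec in params.mediators:
        beta_y = beta_y + spec.b * beta_med[spec.label]

    return Architecture(maf, chrom, pos, ea, oa, beta_x, beta_p, beta_y,
                        beta_med, pleio)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _noisy_table(arch: Architecture, beta_true: np.ndarray, se: np.ndarray,
                 n: float, label: str, trait_type: str,
                 rng: np.random.Generator) -> SummaryTable:
    beta_hat = rng.normal(beta_true, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
    pval = np.maximum(pval, np.finfo(float).tiny)  # keep p in (0, 1]
    df = pd.DataFrame({
        "variant_id": arch.variant_ids, "chrom": arch.chrom, "pos": arch.pos,
        "effect_allele": arch.effect_allele, "other_allele": arch.other_allele,
        "eaf": arch.maf, "beta": beta_hat, "se": se, "pval": pval, "n": float(n),
    }, columns=CANONICAL_COLUMNS)
    return SummaryTable(label, trait_type, df)


def continuous_se(maf: np.ndarray, n: float) -> np.ndarray:
    """Per-variant standard error for a standardised continuous trait."""
    return 1.0 / np.sqrt(n * _het_var(maf))


def logodds_se(maf: np.ndarray, n_cases: float, n_controls: float) -> np.ndarray:
    """Per-variant log-odds standard error via the effective-n approximation.

    n_eff = 4 / (1/cases + 1/controls); var(beta) ~ 4 / (n_eff * 2p(1-p)).
    """
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    return 2.0 / np.sqrt(n_eff * _het_var(maf))


def simulate_summary_stats(arch: Architecture, params: SimulationParams,
                           rng: np.random.Generator | None = None
                           ) -> dict[str, SummaryTable]:
    """Noisy GWAS tables for exposure, proxy, outcome and each mediator."""
    rng = rng or np.random.default_rng(params.seed)
    tables = {
        "exposure": _noisy_table(arch, arch.beta_exposure,
                                 continuous_se(arch.maf, params.n_exposure),
                                 params.n_exposure, "exposure", "continuous", rng),
        "proxy": _noisy_table(arch, arch.beta_proxy,
                              continuous_se(arch.maf, params.n_proxy),
                              params.n_proxy, "proxy", "continuous", rng),
        "outcome": _noisy_table(arch, arch.beta_outcome,
                                logodds_se(arch.maf, params.n_cases, params.n_controls),
                                params.n_cases + params.n_controls,
                                "outcome", "binary", rng),
    }
    for spec in params.mediators:
        tables[spec.label] = _noisy_table(
            arch, arch.beta_mediators[spec.label],
            continuous_se(arch.maf, spec.n_gwas),
            spec.n_gwas, spec.label, "continuous", rng)
    return tables


def ld_reference(arch: Architecture, params: SimulationParams) -> LdReference:
    """Block-diagonal LD: exchangeable r^2 within consecutive variant blocks."""
    ref = LdReference()
    k = params.ld_block_size
    if k <= 1:
        return ref
    ids = arch.variant_ids
    for start in range(0, arch.m, k):
        block = ids[start:start + k]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                ref.add(block[i], block[j], params.ld_r2_within,
                        np.sqrt(params.ld_r2_within))
    return ref


# ---------------------------------------------------------------------------
# individual-level cohort
# ---------------------------------------------------------------------------

def simulate_cohort(arch: Architecture, params: SimulationParams,
                    n: int | None = None,
                    rng: np.random.Generator | None = None) -> CohortData:
    """An independent validation cohort with dosages, phenotypes, covariates.

    Dosages are Binomial(2, maf) (linkage equilibrium); the standardised
    exposure is genetic effects plus small age/sex covariate effects plus
    environmental noise sized so its variance is ~1; mediators follow their
    specs; the binary outcome is Bernoulli under a logistic model whose
    intercept is calibrated so the expected case fraction matches the target.
    """
    rng = rng or np.random.default_rng(params.seed)
    n = n or params.n_cohort
    G = rng.binomial(2, arch.maf, size=(n, arch.m)).astype(float)
    Gc = G - 2.0 * arch.maf  # centred dosages

    age = rng.normal(50.0, 8.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    age_z = (age - 50.0) / 8.0
    sex_z = sex - 0.5
    cov_effect = -0.1 * age_z + 0.1 * sex_z
    cov_var = 0.01 + 0.1**2 * 0.25

    env_var = max(1.0 - params.h2_exposure - cov_var, 0.05)
    x = Gc @ arch.beta_exposure + cov_effect + rng.normal(0, np.sqrt(env_var), n)

    phenos = {"exposure": x}
    linpred = params.theta * x
    for spec in params.mediators:
        delta = arch.beta_mediators[spec.label] - spec.a * arch.beta_exposure
        e_var = max(1.0 - spec.a**2 - spec.h2_specific, 0.05)
        med = spec.a * x + Gc @ delta + rng.normal(0, np.sqrt(e_var), n)
        phenos[spec.label] = med
        linpred = linpred + spec.b * med

    def mean_case(alpha: float) -> float:
        return float(np.mean(expit(alpha + linpred))) - params.case_fraction

    alpha = brentq(mean_case, -30.0, 30.0)
    outcome = rng.binomial(1, expit(alpha + linpred)).astype(float)
    phenos["outcome"] = outcome

    dosages = pd.DataFrame(G, columns=arch.variant_ids)
    meta = pd.DataFrame({
        "variant_id": arch.variant_ids,
        "effect_allele": arch.effect_allele,
        "other_allele": arch.other_allele,
        "eaf": arch.maf,
    })
    covs = pd.DataFrame({"age": age, "sex": sex})
    return CohortData(dosages, pd.DataFrame(phenos), meta, covs)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

SCENARIOS = ("null", "causal", "balanced", "directional", "mediation",
             "triangulation")


def scenario_params(name: str, seed: int = 0) -> SimulationParams:
    """Preset parameters for the named study scenario.

    * ``null`` — no causal effect, no pleiotropy.
    * ``causal`` — causal effect theta = -0.017, valid instruments.
    * ``balanced`` — causal effect plus zero-mean pleiotropy on 30% of variants.
    * ``directional`` — causal effect plus mean-0.01 pleiotropy on 30%.
    * ``mediation`` — one mediator carrying 30% of the total effect
      (direct/total = 0.7).
    * ``triangulation`` — 300-variant shared architecture for proxy-trait
      instrument enlargement with an individual-level validation cohort.

    The estimator-benchmark scenarios draw effect magnitudes from the bounded
    uniform distribution so every variant is a usable instrument (as in a
    selected hit list); the triangulation scenario keeps the normal
    architecture, whose weak tail is what the selection steps act on.
    """
    if name == "null":
        return SimulationParams(m=50, proxy_only_fraction=0.0, r_g=-0.68,
                                theta=0.0, effect_distribution="uniform",
                                seed=seed)
    if name == "causal":
        return SimulationParams(m=50, proxy_only_fraction=0.0, r_g=-0.68,
                                theta=-0.017, effect_distribution="uniform",
                                seed=seed)
    if name == "balanced":
        return SimulationParams(m=50, proxy_only_fraction=0.0, r_g=-0.68,
                                theta=-0.017, pleiotropy_model="balanced",
                                pleiotropy_fraction=0.3, pleiotropy_mean=0.0,
                                pleiotropy_sd=0.01,
                                effect_distribution="uniform", seed=seed)
    if name == "directional":
        return SimulationParams(m=50, proxy_only_fraction=0.0, r_g=-0.68,
                                theta=-0.017, pleiotropy_model="directional",
                                pleiotropy_fraction=0.3, pleiotropy_mean=0.01,
                                pleiotropy_sd=0.005,
                                effect_distribution="uniform", seed=seed)
    if name == "mediation":
        med = MediatorSpec(label="mediator", a=0.3, b=-0.017, h2_specific=0.05)
        # direct effect chosen so direct/total = 0.7 (30% mediated)
        total = -0.017
        return SimulationParams(m=50, proxy_only_fraction=0.0, r_g=-0.68,
                                theta=0.7 * total, mediators=(med,),
                                effect_distribution="uniform", seed=seed)
    if name == "triangulation":
        return SimulationParams(m=300, proxy_only_fraction=0.3, r_g=-0.68,
                                theta=-0.017, n_cohort=10_000, seed=seed)
    raise SimulationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent generators for pipeline stages from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# deterministic instrument-union fixture
# ---------------------------------------------------------------------------

def make_union_fixture(n_exposure_hits: int = 14, n_proxy_hits: int = 148,
                       n_ld_overlap: int = 2, seed: int = 0
                       ) -> tuple[SummaryTable, SummaryTable, SummaryTable, LdReference]:
    """Fixture for the instrument-union rule, SYNTHETIC stand-in for the real
    exposure/proxy hit lists.

    Builds an exposure GWAS containing ``n_exposure_hits`` genome-wide
    significant variants and ``n_proxy_hits`` proxy-trait hits whose
    exposure/proxy effect ratios are exactly proportional (so the radial
    consistency filter keeps all of them) and whose exposure p-values are
    nominally significant; exactly ``n_ld_overlap`` proxy hits are given LD
    r^2 > 0.01 with an exposure hit.  Returns (exposure_hits, proxy_hits,
    exposure_gwas, ld_reference).
    """
    rng = np.random.default_rng(seed)
    m = n_exposure_hits + n_proxy_hits
    maf = rng.uniform(0.1, 0.5, size=m)
    chrom = np.array([str(i % 22 + 1) for i in range(m)])
    pos = np.array([10_000_000 + (i // 22) * 5_000_000 for i in range(m)], dtype=np.int64)
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    ids = [f"fit{i + 1}" for i in range(n_exposure_hits)] + \
          [f"hr{i + 1}" for i in range(n_proxy_hits)]

    se_x = continuous_se(maf, 69_416)
    beta_x = np.empty(m)
    # exposure hits: strongly significant; proxy hits: nominal (|z| ~ 3)
    beta_x[:n_exposure_hits] = 8.0 * se_x[:n_exposure_hits]
    beta_x[n_exposure_hits:] = 3.0 * se_x[n_exposure_hits:] * \
        rng.choice([-1.0, 1.0], size=n_proxy_hits)
    pval_x = 2.0 * stats.norm.sf(np.abs(beta_x / se_x))

    def table(label, idx, beta, se, pval, n):
        df = pd.DataFrame({
            "variant_id": [ids[i] for i in idx], "chrom": chrom[idx], "pos": pos[idx],
            "effect_allele": [pairs[i][0] for i in idx],
            "other_allele": [pairs[i][1] for i in idx],
            "eaf": maf[idx], "beta": beta, "se": se, "pval": pval, "n": float(n),
        }, columns=CANONICAL_COLUMNS)
        return SummaryTable(label, "continuous", df)

    all_idx = np.arange(m)
    exposure_gwas = table("exposure", all_idx, beta_x, se_x, pval_x, 69_416)
    exposure_hits = table("exposure", all_idx[:n_exposure_hits],
                          beta_x[:n_exposure_hits], se_x[:n_exposure_hits],
                          pval_x[:n_exposure_hits], 69_416)

    # proxy-trait GWAS for the proxy hits: exposure effect exactly -0.4 times
    # the proxy effect, so every ratio is identical (zero radial heterogeneity)
    p_idx = all_idx[n_exposure_hits:]
    beta_p = beta_x[n_exposure_hits:] / -0.4
    se_p = continuous_se(maf[p_idx], 452_941)
    pval_p = np.full(n_proxy_hits, 1e-10)
    proxy_hits = table("proxy", p_idx, beta_p, se_p, pval_p, 452_941)

    ld = LdReference()
    for k in range(n_ld_overlap):
        ld.add(ids[n_exposure_hits + k], ids[k], 0.5, 0.9)
    return exposure_hits, proxy_hits, exposure_gwas, ld
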