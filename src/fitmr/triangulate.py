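"""Proxy-trait triangulation of genetic instruments.

An under-powered exposure GWAS (here, exercise-test cardiorespiratory
fitness) yields few genome-wide significant variants.  A genetically
correlated, well-powered proxy trait (resting heart rate) supplies many more
hits; radial filtering of those hits against the exposure GWAS keeps the ones
whose exposure/proxy effect ratios are mutually consistent and sign-concordant
with the pooled ratio.  Four candidate instruments are built and compared by
the phenotypic variance they explain in an independent validation cohort:

* I1 — exposure-GWAS genome-wide significant variants;
* I2 — proxy-trait hits passing the radial consistency filter;
* I3 — the subset of I2 nominally associated with the exposure;
* I4 — the union of I1 and I3, keeping the I1 member of any cross pair in
  LD (r^2 above a small threshold).

All weights are per-allele exposure effects oriented to the
exposure-increasing allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mr
from .grs import CohortData, compute_grs, decile_means, variance_explained
from .sumstats import (HarmonisedSet, LdReference, SummaryTable, SumstatsError,
                       harmonise_pair, log_drop)

logger = logging.getLogger("fitmr")


class TriangulationError(ValueError):
    """Instrument construction could not proceed."""


@dataclass(frozen=True)
class InstrumentMember:
    variant_id: str
    effect_allele: str
    weight: float                  # exposure beta per exposure-increasing allele
    source: str                    # "exercise_gwas" | "proxy_trait"


@dataclass
class InstrumentSet:
    """A labelled, weighted variant list with per-member provenance."""

    label: str
    members: list[InstrumentMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.variant_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise TriangulationError(f"duplicate variants in instrument {self.label}")
        if any(m.weight <= 0 for m in self.members):
            raise TriangulationError("instrument weights must be positive "
                                     "(exposure-increasing orientation)")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def variant_ids(self) -> list[str]:
        return [m.variant_id for m in self.members]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.__dict__ for m in self.members],
                            columns=["variant_id", "effect_allele", "weight", "source"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str) -> "InstrumentSet":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls(label, [InstrumentMember(str(r.variant_id), str(r.effect_allele),
                                            float(r.weight), str(r.source))
                           for r in df.itertuples(index=False)])


@dataclass
class ValidationResult:
    label: str
    r_squared: float
    p: float
    decile_means: np.ndarray   # mean phenotype per score decile, ascending
    n_members: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise TriangulationError(f"R^2 out of [0,1]: {self.r_squared}")
        if len(self.decile_means) != 10:
            raise TriangulationError("decile means must have length 10")


# ---------------------------------------------------------------------------
# radial consistency filtering of proxy-trait hits
# ---------------------------------------------------------------------------

def radial_proxy_filter(proxy_vs_exposure: HarmonisedSet, alpha: float = 0.05,
                        require_sign_consistency: bool = True,
                        require_q: bool = True) -> tuple[list[str], list[str]]:
    """Select proxy-trait variants with effects consistent with the exposure.

    ``proxy_vs_exposure`` is harmonised with the proxy trait in the exposure
    role and the target exposure in the outcome role.  The radial IVW model
    is fit iteratively; variants flagged as heterogeneity outliers
    (per-variant Q contribution significant at ``alpha``) are removed, and
    variants whose individual ratio disagrees in sign with the pooled radial
    estimate are removed as inconsistent.  Either criterion can be switched
    off.  Returns (kept, removed) variant-id lists.
    """
    if len(proxy_vs_exposure) < 3:
        raise TriangulationError("radial proxy filtering needs at least 3 variants")
    current = proxy_vs_exposure
    removed: list[str] = []
    if require_q:
        current, removed = mr.radial_outlier_filter(current, alpha=alpha)
    if len(current) >= 3:
        beta, _, _ = mr.radial_fit(current)
    else:
        beta = mr.ivw(current, "fixed").beta
    if require_sign_consistency:
        r = current.df["beta_out"].to_numpy(float) / current.df["beta_exp"].to_numpy(float)
        bad = np.sign(r) != np.sign(beta)
        ids = [v for v, b in zip(current.df["variant_id"], bad) if b]
        for vid in ids:
            log_drop("radial_proxy", vid, "sign_inconsistent")
        removed.extend(ids)
        current = current.subset([v for v in current.df["variant_id"]
                                  if v not in set(ids)])
    return list(current.df["variant_id"]), removed


# ---------------------------------------------------------------------------
# instrument construction
# ---------------------------------------------------------------------------

def _exposure_weight(row) -> tuple[str, float]:
    """Effect allele and weight oriented to the exposure-increasing allele."""
    if row["beta"] >= 0:
        return str(row["effect_allele"]), float(row["beta"])
    return str(row["other_allele"]), float(-row["beta"])


def build_instrument_sets(exposure_hits: SummaryTable, proxy_hits: SummaryTable,
                          exposure_gwas: SummaryTable, ld_ref: LdReference,
                          alpha_radial: float = 0.05, p_nominal: float = 0.05,
                          r2_union: float = 0.01,
                          use_proxies: bool = False) -> dict[str, InstrumentSet]:
    """Build the four candidate instruments (I1-I4).

    ``exposure_hits`` are the exposure GWAS's independent significant
    variants; ``proxy_hits`` the proxy trait's.  Proxy hits are harmonised
    against the full exposure GWAS (proxy as exposure), radial-filtered for
    consistency, thinned to nominal exposure significance (I3), and merged
    with I1 under the LD-prioritisation rule: for any cross pair with
    r^2 > ``r2_union`` the exposure-GWAS member is kept and the proxy member
    dropped (proxy members considered in ascending exposure p).  Weights are
    exposure-GWAS betas, exposure-increasing orientation.
    """
    if len(exposure_hits) == 0:
        raise TriangulationError("no exposure-GWAS significant hits (I1 empty)")

    i1_members = []
    for row in exposure_hits.df.to_dict("records"):
        ea, w = _exposure_weight(row)
        i1_members.append(InstrumentMember(row["variant_id"], ea, w, "exercise_gwas"))
    i1 = InstrumentSet("I1", i1_members)

    # proxy trait in the exposure role, target exposure GWAS in the outcome role
    pve = harmonise_pair(proxy_hits, exposure_gwas, ld_ref=ld_ref,
                         use_proxies=use_proxies)
    kept, _ = radial_proxy_filter(pve, alpha=alpha_radial)
    kept_df = pve.df[pve.df["variant_id"].isin(kept)]

    exp_by_id = {r["variant_id"]: r for r in exposure_gwas.df.to_dict("records")}

    def proxy_member(vid: str) -> InstrumentMember:
        row = exp_by_id[vid]
        ea, w = _exposure_weight(row)
        return InstrumentMember(vid, ea, w, "proxy_trait")

    i2_ids = [v for v in kept_df["variant_id"] if v in exp_by_id]
    i2 = InstrumentSet("I2", [proxy_member(v) for v in i2_ids])

    i3_rows = [(v, exp_by_id[v]["pval"], exp_by_id[v]["pos"]) for v in i2_ids
               if exp_by_id[v]["pval"] < p_nominal]
    i3 = InstrumentSet("I3", [proxy_member(v) for v, _, _ in i3_rows])

    i4_members = list(i1_members)
    if len(i3) == 0:
        logger.warning("event=empty_instrument label=I3 fallback=I1")
    i1_ids = set(i1.variant_ids)
    # greedy over proxy members in ascending exposure p (ties: position, id)
    for vid, _, _ in sorted(i3_rows, key=lambda t: (t[1], t[2], t[0])):
        if vid in i1_ids:
            log_drop("instrument_union", vid, "already_in_exposure_set")
            continue
        hit = next((e for e in i1_ids if ld_ref.r2(vid, e) > r2_union), None)
        if hit is not None:
            log_drop("instrument_union", vid, "ld_with_exposure_hit",
                     partner=hit, r2=ld_ref.r2(vid, hit))
            continue
        i4_members.append(proxy_member(vid))
    i4 = InstrumentSet("I4", i4_members)
    return {"I1": i1, "I2": i2, "I3": i3, "I4": i4}


# ---------------------------------------------------------------------------
# validation in an independent cohort
# ---------------------------------------------------------------------------

def validate_instrument(instrument: InstrumentSet, cohort: CohortData,
                        phenotype: str = "exposure") -> ValidationResult:
    """Score the cohort and measure variance explained in the phenotype."""
    score = compute_grs(cohort, instrument)
    if np.std(score) == 0:
        raise TriangulationError("instrument score has zero variance in cohort")
    pheno = cohort.phenotypes[phenotype].to_numpy(float)
    r2, p = variance_explained(score, pheno, cohort.covariates)
    return ValidationResult(instrument.label, max(r2, 0.0), p,
                            decile_means(score, pheno), len(instrument))


def select_instrument(validations: list[ValidationResult]) -> str:
    """Label of the strongest instrument: max R^2, then smaller p, then fewer members."""
    if not validations:
        raise TriangulationError("no validations supplied")
    best = min(validations, key=lambda v: (-v.r_squared, v.p, v.n_members))
    return best.label
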