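"""GWAS summary-statistics tables: reading, validation, clumping, harmonisation.

Summary statistics are held as pandas DataFrames in a canonical column layout
(``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n``).
Harmonisation aligns an exposure and an outcome GWAS to a common effect allele,
optionally recruiting high-LD proxies for variants absent from the outcome, and
orients every retained variant to the exposure-increasing allele so downstream
instrumental-variable weights are positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("fitmr")

#: canonical column order for summary-statistics TSVs
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

VALID_ALLELES = {"A", "C", "G", "T"}
PALINDROMIC_SETS = ({"A", "T"}, {"C", "G"})

#: effect-allele frequency band inside which a palindromic variant's strand
#: cannot be resolved by frequency matching and the variant is dropped
PALINDROMIC_EAF_BAND = (0.42, 0.58)


class SumstatsError(ValueError):
    """Configuration or content error in a summary-statistics table."""


def log_drop(stage: str, variant_id: str, reason: str, **extra) -> None:
    """Emit one structured line per variant dropped by any filtering stage."""
    kv = " ".join(f"{k}={v}" for k, v in extra.items())
    logger.warning("event=variant_dropped stage=%s variant=%s reason=%s %s",
                   stage, variant_id, reason, kv)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float          # may be NaN when unknown
    beta: float
    se: float
    pval: float
    n: float

    def validate(self) -> str | None:
        """Return a rejection reason, or None if the record is well formed."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not np.isfinite(self.se) or self.se <= 0:
            return "nonpositive_se"
        if np.isfinite(self.eaf) and not (0.0 < self.eaf < 1.0):
            return "eaf_out_of_range"
        if not (0.0 < self.pval <= 1.0):
            return "pval_out_of_range"
        if self.pos < 1:
            return "nonpositive_position"
        if not self.n > 0:
            return "nonpositive_n"
        return None

    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in PALINDROMIC_SETS


@dataclass
class SummaryTable:
    """A labelled GWAS summary-statistics table with unique variant ids."""

    trait_label: str
    trait_type: str  # "continuous" | "binary"
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SumstatsError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"missing canonical columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise SumstatsError(f"duplicate variant ids: {sorted(set(dups))[:5]}")
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.df["variant_id"])

    def get(self, variant_id: str) -> VariantAssociation:
        row = self.df.loc[self.df["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        return VariantAssociation(**row.iloc[0].to_dict())

    def subset(self, variant_ids: Iterable[str]) -> "SummaryTable":
        ids = list(variant_ids)
        sub = self.df[self.df["variant_id"].isin(ids)]
        return SummaryTable(self.trait_label, self.trait_type, sub.copy())

    @classmethod
    def from_records(cls, trait_label: str, trait_type: str,
                     records: Iterable[VariantAssociation]) -> "SummaryTable":
        df = pd.DataFrame([r.__dict__ for r in records], columns=CANONICAL_COLUMNS)
        return cls(trait_label, trait_type, df)


class LdReference:
    """Symmetric pairwise LD lookup: (id_a, id_b) -> r^2 and optional D'."""

    def __init__(self) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        self._dprime: dict[tuple[str, str], float] = {}
        self._neighbours: dict[str, set[str]] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float, dprime: float | None = None) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise SumstatsError(f"r2 out of [0,1]: {r2}")
        if dprime is not None and not (0.0 <= dprime <= 1.0):
            raise SumstatsError(f"dprime out of [0,1]: {dprime}")
        k = self._key(a, b)
        self._r2[k] = r2
        if dprime is not None:
            self._dprime[k] = dprime
        self._neighbours.setdefault(a, set()).add(b)
        self._neighbours.setdefault(b, set()).add(a)

    def r2(self, a: str, b: str) -> float:
        """r^2 between two variants; a variant with itself is 1, unknown pairs 0."""
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def dprime(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        return self._dprime.get(self._key(a, b))

    def neighbours(self, a: str) -> set[str]:
        return self._neighbours.get(a, set())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdReference":
        ref = cls()
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        cols = list(df.columns)
        if len(cols) < 3:
            raise SumstatsError("LD reference needs at least 3 columns (id_a, id_b, r2)")
        for row in df.itertuples(index=False):
            dprime = float(row[3]) if len(cols) > 3 and pd.notna(row[3]) else None
            ref.add(str(row[0]), str(row[1]), float(row[2]), dprime)
        return ref

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"id_a": a, "id_b": b, "r2": r2, "dprime": self._dprime.get((a, b), np.nan)}
            for (a, b), r2 in sorted(self._r2.items())
        ]
        pd.DataFrame(rows, columns=["id_a", "id_b", "r2", "dprime"]).to_csv(
            path, sep="\t", index=False)


#: columns of the harmonised DataFrame (mediator columns appended as
#: ``beta_med_<label>`` / ``se_med_<label>``)
HARMONISED_COLUMNS = [
    "variant_id", "effect_allele", "other_allele", "eaf",
    "beta_exp", "se_exp", "pval_exp", "n_exp",
    "beta_out", "se_out", "pval_out", "n_out",
    "allele_flipped", "strand_flipped", "proxy_id",
]


@dataclass
class HarmonisedSet:
    """Exposure/outcome effect pairs aligned to the exposure-increasing allele.

    ``df`` has one row per retained variant with exposure effects strictly
    positive; ``dropped`` records every exposure variant that could not be
    harmonised, with the reason.  Mediator GWAS effects attached later live in
    ``beta_med_<label>`` / ``se_med_<label>`` columns.
    """

    exposure_label: str
    outcome_label: str
    df: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"]))
    mediator_labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, variant_ids: Iterable[str]) -> "HarmonisedSet":
        ids = set(variant_ids)
        return HarmonisedSet(
            self.exposure_label, self.outcome_label,
            self.df[self.df["variant_id"].isin(ids)].reset_index(drop=True),
            self.dropped.copy(), list(self.mediator_labels))

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out,
                    variant_ids=None, n_exp=np.nan, n_out=np.nan,
                    exposure_label="exposure", outcome_label="outcome",
                    mediators: Mapping[str, tuple] | None = None) -> "HarmonisedSet":
        """Build a harmonised set directly from aligned effect arrays.

        Orientation to the exposure-increasing allele is applied (rows with
        negative exposure effects have both effects negated).
        """
        bx = np.asarray(beta_exp, dtype=float).copy()
        by = np.asarray(beta_out, dtype=float).copy()
        flip = bx < 0
        bx[flip] *= -1
        by[flip] *= -1
        m = len(bx)
        if variant_ids is None:
            variant_ids = [f"v{i}" for i in range(m)]
        df = pd.DataFrame({
            "variant_id": list(variant_ids),
            "effect_allele": "A", "other_allele": "G", "eaf": np.nan,
            "beta_exp": bx, "se_exp": np.asarray(se_exp, dtype=float),
            "pval_exp": np.nan, "n_exp": n_exp,
            "beta_out": by, "se_out": np.asarray(se_out, dtype=float),
            "pval_out": np.nan, "n_out": n_out,
            "allele_flipped": False, "strand_flipped": False, "proxy_id": None,
        })
        labels = []
        if mediators:
            for lab, (bm, sm) in mediators.items():
                bm = np.asarray(bm, dtype=float).copy()
                bm[flip] *= -1
                df[f"beta_med_{lab}"] = bm
                df[f"se_med_{lab}"] = np.asarray(sm, dtype=float)
                labels.append(lab)
        return cls(exposure_label, outcome_label, df, mediator_labels=labels)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_summary_table(path: str | Path,
                       dialect: Mapping[str, str] | None = None,
                       trait_label: str | None = None,
                       trait_type: str = "continuous") -> SummaryTable:
    """Read a TSV of GWAS summary statistics into a validated table.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    dialect
        Mapping from canonical column name to the column name used in the
        file, e.g. ``{"variant_id": "rsid", "pval": "p"}``.  Unmapped
        canonical names are looked up verbatim.
    trait_label
        Defaults to the file stem.
    trait_type
        ``"continuous"`` or ``"binary"`` (betas on the log-odds scale).

    Rows violating per-variant invariants (non-positive se, frequency outside
    (0,1), ...) are rejected with a logged reason; an error is raised only if
    a mandatory column is missing or no row survives.
    """
    path = Path(path)
    if not path.exists():
        raise SumstatsError(f"no such file: {path}")
    dialect = dict(dialect or {})
    raw = pd.read_csv(path, sep="\t", dtype={dialect.get("chrom", "chrom"): str},
                      na_values=["NA", "", "."])
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = dialect.get(canon, canon)
        if src not in raw.columns:
            if canon == "eaf":  # eaf is the only optional column
                raw[canon] = np.nan
                continue
            raise SumstatsError(f"mandatory column {src!r} (for {canon!r}) "
                                f"absent from {path.name}")
        rename[src] = canon
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS].copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    keep = np.ones(len(df), dtype=bool)
    for i, rec in enumerate(df.to_dict("records")):
        reason = VariantAssociation(**rec).validate()
        if reason is not None:
            keep[i] = False
            log_drop("read", rec["variant_id"], reason, file=path.name)
    if not keep.any():
        raise SumstatsError(f"all {len(df)} rows of {path.name} rejected")
    return SummaryTable(trait_label or path.stem, trait_type,
                        df.loc[keep].reset_index(drop=True))


def write_summary_table(table: SummaryTable, path: str | Path) -> None:
    """Write a table in the canonical TSV layout (round-trips exactly)."""
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# distance clumping
# ---------------------------------------------------------------------------

def distance_clump(table: SummaryTable, window: int = 1_000_000,
                   p_max: float = 5e-8) -> SummaryTable:
    """Greedy distance-based clumping of a summary table.

    Variants are visited in order of ascending p (ties: smaller position, then
    lexicographic id); each retained variant suppresses all not-yet-retained
    variants on the same chromosome within ``window`` base pairs (distance
    <= window counts as within).  Only variants with p <= p_max enter.
    """
    df = table.df[table.df["pval"] <= p_max]
    if df.empty:
        logger.warning("event=empty_clump trait=%s p_max=%g", table.trait_label, p_max)
        return SummaryTable(table.trait_label, table.trait_type,
                            table.df.iloc[0:0].copy())
    df = df.sort_values(["pval", "pos", "variant_id"],
                        kind="mergesort").reset_index(drop=True)
    retained: list[int] = []
    occupied: dict[str, list[int]] = {}
    for i, (chrom, pos) in enumerate(zip(df["chrom"], df["pos"])):
        taken = occupied.get(chrom, [])
        if any(abs(pos - q) <= window for q in taken):
            log_drop("clump", df["variant_id"].iat[i], "within_window",
                     trait=table.trait_label)
            continue
        retained.append(i)
        occupied.setdefault(chrom, []).append(pos)
    out = df.iloc[retained].sort_values(
        ["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SummaryTable(table.trait_label, table.trait_type, out)


# ---------------------------------------------------------------------------
# proxy lookup
# ---------------------------------------------------------------------------

def find_proxy(target: str, outcome_table: SummaryTable, ld_ref: LdReference,
               r2_min: float = 0.8, dprime_min: float = 0.8) -> str | None:
    """Best available LD proxy for ``target`` among the outcome table's variants.

    Candidates need r^2 > r2_min and, when D' is recorded, D' > dprime_min.
    The candidate with the smallest outcome p wins; ties break to higher r^2,
    then lexicographic id.  Returns None when no candidate qualifies.
    """
    present = set(outcome_table.df["variant_id"])
    cands = []
    for vid in ld_ref.neighbours(target):
        if vid not in present:
            continue
        r2 = ld_ref.r2(target, vid)
        if r2 <= r2_min:
            continue
        dp = ld_ref.dprime(target, vid)
        if dp is not None and dp <= dprime_min:
            continue
        pval = float(outcome_table.df.loc[
            outcome_table.df["variant_id"] == vid, "pval"].iloc[0])
        cands.append((pval, -r2, vid))
    if not cands:
        return None
    cands.sort()
    return cands[0][2]


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def _complement(allele: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[allele]


def harmonise_pair(exposure: SummaryTable, outcome: SummaryTable,
                   ld_ref: LdReference | None = None,
                   use_proxies: bool = False,
                   palindromic_band: tuple[float, float] = PALINDROMIC_EAF_BAND,
                   ) -> HarmonisedSet:
    """Align exposure and outcome effects to the exposure-increasing allele.

    For each exposure variant found in the outcome table (directly, or through
    a high-LD proxy when ``use_proxies``), allele labels are reconciled: a
    swapped label pair negates the outcome beta and mirrors its frequency.
    Palindromic variants (A/T, C/G) are dropped when the exposure frequency
    falls inside ``palindromic_band`` (or is missing) and otherwise aligned by
    matching minor-allele side.  Finally both effects are oriented so the
    exposure beta is positive.  Variants whose allele sets neither match nor
    swap are dropped with a warning.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise SumstatsError("harmonise_pair requires non-empty tables")
    out_by_id = {r["variant_id"]: r for r in outcome.df.to_dict("records")}
    lo, hi = palindromic_band
    rows: list[dict] = []
    dropped: list[dict] = []

    for ev in exposure.df.to_dict("records"):
        vid = ev["variant_id"]
        proxy_id = None
        ov = out_by_id.get(vid)
        if ov is None and use_proxies and ld_ref is not None:
            proxy_id = find_proxy(vid, outcome, ld_ref)
            if proxy_id is not None:
                ov = out_by_id[proxy_id]
        if ov is None:
            dropped.append({"variant_id": vid, "reason": "absent_from_outcome"})
            log_drop("harmonise", vid, "absent_from_outcome")
            continue

        beta_out, se_out = ov["beta"], ov["se"]
        eaf_out = ov["eaf"]
        flipped = False
        strand = False

        if proxy_id is None:
            ea, oa = ev["effect_allele"], ev["other_allele"]
            pal = {ea, oa} in PALINDROMIC_SETS
            if (ov["effect_allele"], ov["other_allele"]) == (ea, oa):
                pass
            elif (ov["effect_allele"], ov["other_allele"]) == (oa, ea):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out if np.isfinite(eaf_out) else np.nan
                flipped = True
            elif not pal and (ov["effect_allele"], ov["other_allele"]) == (
                    _complement(ea), _complement(oa)):
                strand = True  # reported on the opposite strand, same orientation
            elif not pal and (ov["effect_allele"], ov["other_allele"]) == (
                    _complement(oa), _complement(ea)):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out if np.isfinite(eaf_out) else np.nan
                flipped = True
                strand = True
            else:
                dropped.append({"variant_id": vid, "reason": "allele_mismatch"})
                log_drop("harmonise", vid, "allele_mismatch")
                continue
            if pal:
                eaf_exp = ev["eaf"]
                if not np.isfinite(eaf_exp) or lo < eaf_exp < hi:
                    dropped.append({"variant_id": vid, "reason": "palindromic"})
                    log_drop("harmonise", vid, "palindromic", eaf=eaf_exp)
                    continue
                # frequency alignment: discordant minor-allele side means the
                # outcome reported the complementary strand orientation
                if np.isfinite(eaf_out) and (eaf_exp < 0.5) != (eaf_out < 0.5):
                    beta_out = -beta_out
                    eaf_out = 1.0 - eaf_out
                    strand = True
        else:
            # proxy variant: different alleles; orient by frequency concordance
            eaf_exp, eaf_prox = ev["eaf"], ov["eaf"]
            if (not np.isfinite(eaf_exp) or not np.isfinite(eaf_prox)
                    or lo < eaf_exp < hi or lo < eaf_prox < hi):
                dropped.append({"variant_id": vid, "reason": "proxy_ambiguous"})
                log_drop("harmonise", vid, "proxy_ambiguous", proxy=proxy_id)
                continue
            if (eaf_exp < 0.5) != (eaf_prox < 0.5):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out

        beta_exp, se_exp = ev["beta"], ev["se"]
        ea, oa, eaf = ev["effect_allele"], ev["other_allele"], ev["eaf"]
        if beta_exp < 0:  # orient to the exposure-increasing allele
            beta_exp, beta_out = -beta_exp, -beta_out
            ea, oa = oa, ea
            eaf = 1.0 - eaf if np.isfinite(eaf) else np.nan
        rows.append({
            "variant_id": vid, "effect_allele": ea, "other_allele": oa,
            "eaf": eaf,
            "beta_exp": beta_exp, "se_exp": se_exp,
            "pval_exp": ev["pval"], "n_exp": ev["n"],
            "beta_out": beta_out, "se_out": se_out,
            "pval_out": ov["pval"], "n_out": ov["n"],
            "allele_flipped": flipped, "strand_flipped": strand,
            "proxy_id": proxy_id,
        })

    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=HARMONISED_COLUMNS)
    return HarmonisedSet(exposure.trait_label, outcome.trait_label, df,
                         pd.DataFrame(dropped, columns=["variant_id", "reason"]))


def add_mediator(h: HarmonisedSet, mediator: SummaryTable,
                 ld_ref: LdReference | None = None,
                 use_proxies: bool = False) -> HarmonisedSet:
    """Attach a mediator GWAS to a harmonised set (for multivariable MR).

    The mediator's effects are aligned to each retained variant's effect
    allele; variants missing from the mediator GWAS (after optional proxy
    lookup) are dropped from the set with a warning.
    """
    med_by_id = {r["variant_id"]: r for r in mediator.df.to_dict("records")}
    lab = mediator.trait_label
    beta_m, se_m, keep = [], [], []
    for row in h.df.to_dict("records"):
        vid = row["variant_id"]
        mv = med_by_id.get(vid)
        if mv is None and use_proxies and ld_ref is not None:
            pid = find_proxy(vid, mediator, ld_ref)
            mv = med_by_id.get(pid) if pid else None
        if mv is None:
            log_drop("mediator", vid, "absent_from_mediator", mediator=lab)
            keep.append(False)
            continue
        b = mv["beta"]
        if (mv["effect_allele"], mv["other_allele"]) == (
                row["effect_allele"], row["other_allele"]):
            pass
        elif (mv["effect_allele"], mv["other_allele"]) == (
                row["other_allele"], row["effect_allele"]):
            b = -b
        else:
            log_drop("mediator", vid, "allele_mismatch", mediator=lab)
            keep.append(False)
            continue
        beta_m.append(b)
        se_m.append(mv["se"])
        keep.append(True)
    df = h.df.loc[keep].reset_index(drop=True)
    df[f"beta_med_{lab}"] = beta_m
    df[f"se_med_{lab}"] = se_m
    return HarmonisedSet(h.exposure_label, h.outcome_label, df, h.dropped,
                         h.mediator_labels + [lab])


def write_harmonised(h: HarmonisedSet, path: str | Path) -> None:
    h.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_harmonised(path: str | Path, exposure_label: str = "exposure",
                    outcome_label: str = "outcome") -> HarmonisedSet:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    labels = [c[len("beta_med_"):] for c in df.columns if c.startswith("beta_med_")]
    if "proxy_id" in df.columns:
        df["proxy_id"] = df["proxy_id"].astype(object).where(df["proxy_id"].notna(), None)
    return HarmonisedSet(exposure_label, outcome_label, df, mediator_labels=labels)
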