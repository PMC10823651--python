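"""GWAS summary-statistic containers, TSV I/O, allele harmonisation, and
instrument-strength statistics.

An :class:`AssociationTable` is a thin, validated wrapper around a pandas
DataFrame holding one association per variant for one trait measured in one
sample (columns ``variant_id, effect_allele, other_allele, eaf, beta, se, n,
p``).  Betas are per copy of the effect allele — log odds ratios for binary
traits, SD units for continuous ones.

Harmonisation aligns an outcome table to the effect alleles of an exposure
table, the prerequisite for two-sample Mendelian randomisation: swapped
alleles flip the beta sign and the allele frequency, strand flips are
resolved through base complements, and palindromic variants (A/T, C/G) are
resolved by allele-frequency concordance or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("variant_id", "effect_allele", "other_allele",
                     "eaf", "beta", "se", "n")
#: |eaf - 0.5| must exceed this on both sides for a palindromic variant to be
#: resolved by frequency concordance; closer to 0.5 the strands are
#: indistinguishable and the variant is dropped.
PALINDROMIC_EAF_THRESHOLD = 0.08

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SummaryAssociation:
    """A single variant-trait association from a GWAS."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    n: float
    p: float | None = None

    def __post_init__(self):
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant_id}: eaf must be in (0,1)")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: alleles must differ")


def _p_from_z(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(np.asarray(beta) / np.asarray(se)))


class AssociationTable:
    """Ordered collection of per-variant associations for one trait/sample."""

    def __init__(self, df: pd.DataFrame, trait: str = "", sample: str = ""):
        df = df.copy().reset_index(drop=True)
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
        for col in ("eaf", "beta", "se", "n"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        if df["variant_id"].duplicated().any():
            dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ValueError(f"duplicate variant_id: {dups}")
        if (df["se"] <= 0).any():
            raise ValueError("all se must be > 0")
        if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
            raise ValueError("all eaf must be in (0,1)")
        if (df["effect_allele"] == df["other_allele"]).any():
            raise ValueError("effect and other allele must differ")
        if "p" not in df.columns:
            df["p"] = _p_from_z(df["beta"].to_numpy(), df["se"].to_numpy())
        else:
            df["p"] = pd.to_numeric(df["p"], errors="raise")
            miss = df["p"].isna()
            if miss.any():
                df.loc[miss, "p"] = _p_from_z(df.loc[miss, "beta"].to_numpy(),
                                              df.loc[miss, "se"].to_numpy())
        self.df = df
        self.trait = trait
        self.sample = sample

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield SummaryAssociation(row.variant_id, row.effect_allele,
                                     row.other_allele, row.eaf, row.beta,
                                     row.se, row.n, row.p)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    @classmethod
    def from_tsv(cls, path, trait: str = "", sample: str = "") -> "AssociationTable":
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str,
                                                "effect_allele": str,
                                                "other_allele": str})
        return cls(df, trait=trait, sample=sample)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def restrict(self, variant_ids) -> "AssociationTable":
        return restrict_to_subset(self, variant_ids)


def read_summary_table(path, trait: str = "", sample: str = "") -> AssociationTable:
    return AssociationTable.from_tsv(path, trait=trait, sample=sample)


def write_summary_table(table: AssociationTable, path) -> None:
    table.to_tsv(path)


def restrict_to_subset(table: AssociationTable, variant_ids) -> AssociationTable:
    """Keep the intersection with `variant_ids`, preserving table order."""
    keep = set(variant_ids)
    sub = table.df[table.df["variant_id"].isin(keep)]
    if sub.empty:
        raise ValueError("no variants left after restriction")
    return AssociationTable(sub, trait=table.trait, sample=table.sample)


def is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonise(exposure: AssociationTable, outcome: AssociationTable,
              palindromic_eaf_threshold: float = PALINDROMIC_EAF_THRESHOLD,
              ) -> AssociationTable:
    """Align `outcome` to the effect alleles of `exposure`.

    Per shared variant: matching alleles pass through; swapped alleles negate
    the outcome beta and flip its eaf; strand-complement representations are
    resolved the same way; palindromic variants are resolved by eaf
    concordance when both frequencies are at least `palindromic_eaf_threshold`
    away from 0.5, otherwise dropped.  Variants absent from either table, or
    with irreconcilable alleles, are dropped with a logged count.
    """
    exp = exposure.df.set_index("variant_id")
    out = outcome.df.set_index("variant_id")
    shared = [v for v in exposure.variant_ids if v in out.index]
    if not shared:
        raise ValueError("no shared variants between exposure and outcome")

    rows, n_dropped = [], 0
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        ea, oa = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        oea, ooa = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        rec = o.to_dict()
        rec["variant_id"] = vid

        if is_palindromic(ea, oa):
            # same base pair on either strand: use allele frequencies
            if {oea, ooa} != {ea, oa}:
                n_dropped += 1
                continue
            de = e["eaf"] - 0.5
            do = o["eaf"] - 0.5
            if abs(de) <= palindromic_eaf_threshold or abs(do) <= palindromic_eaf_threshold:
                n_dropped += 1
                continue
            if de * do < 0:  # frequencies disagree -> effect alleles opposed
                rec["beta"] = -o["beta"]
                rec["eaf"] = 1.0 - o["eaf"]
            rec["effect_allele"], rec["other_allele"] = ea, oa
        elif (oea, ooa) == (ea, oa):
            pass
        elif (oea, ooa) == (oa, ea):
            rec["beta"] = -o["beta"]
            rec["eaf"] = 1.0 - o["eaf"]
            rec["effect_allele"], rec["other_allele"] = ea, oa
        elif (_COMPLEMENT.get(oea), _COMPLEMENT.get(ooa)) == (ea, oa):
            rec["effect_allele"], rec["other_allele"] = ea, oa
        elif (_COMPLEMENT.get(oea), _COMPLEMENT.get(ooa)) == (oa, ea):
            rec["beta"] = -o["beta"]
            rec["eaf"] = 1.0 - o["eaf"]
            rec["effect_allele"], rec["other_allele"] = ea, oa
        else:
            n_dropped += 1
            continue
        rows.append(rec)

    n_unshared = len(exposure) - len(shared)
    if n_dropped or n_unshared:
        logger.info("harmonise: dropped %d incompatible and %d unshared variants",
                    n_dropped, n_unshared)
    if not rows:
        raise ValueError("no variants survived harmonisation")
    df = pd.DataFrame(rows)
    df = df[[c for c in outcome.df.columns]]
    return AssociationTable(df, trait=outcome.trait, sample=outcome.sample)


def harmonised_frame(exposure: AssociationTable, outcome: AssociationTable,
                     **kwargs) -> pd.DataFrame:
    """Harmonise and merge into one frame with bx/sx (exposure), by/sy (outcome)."""
    aligned = harmonise(exposure, outcome, **kwargs)
    e = exposure.df.rename(columns={"beta": "bx", "se": "sx", "eaf": "eaf_exposure"})
    o = aligned.df.rename(columns={"beta": "by", "se": "sy", "eaf": "eaf_outcome"})
    merged = e.merge(o[["variant_id", "by", "sy", "eaf_outcome"]], on="variant_id",
                     how="inner")
    return merged


def instrument_strength(exposure: AssociationTable) -> tuple[float, float]:
    """Mean per-variant F statistic and total variance explained.

    F_j = (beta_j / se_j)^2 from summary data; r2_j = 2 f_j (1 - f_j) beta_j^2
    under a standardized trait.  Returns (mean_F, total_R2).
    """
    beta = exposure.df["beta"].to_numpy(float)
    se = exposure.df["se"].to_numpy(float)
    eaf = exposure.df["eaf"].to_numpy(float)
    f_stats = (beta / se) ** 2
    r2 = 2.0 * eaf * (1.0 - eaf) * beta ** 2
    return float(f_stats.mean()), float(r2.sum())
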