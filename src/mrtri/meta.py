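"""Inverse-variance meta-analysis across cohorts (and across SNPs).

Fixed-effect pooling weights each study by its inverse squared standard
error; the DerSimonian-Laird random-effects variant adds a method-of-
moments between-study variance tau^2 derived from Cochran's Q.  Per-SNP
cross-cohort pooling aligns tables on variant id and pools each SNP over
the cohorts that measured it, which is how cohorts genotyped on a 12-SNP
subset still contribute to a 97-SNP analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .summary import AssociationTable

logger = logging.getLogger(__name__)


@dataclass
class MetaResult:
    """Pooled effect with heterogeneity diagnostics."""

    pooled_effect: float
    pooled_se: float
    k: int
    Q: float
    df: int
    p_Q: float
    tau2: float
    method: str  # "fixed" | "dersimonian_laird"

    @property
    def ci(self) -> tuple[float, float]:
        z = stats.norm.ppf(0.975)
        return (self.pooled_effect - z * self.pooled_se,
                self.pooled_effect + z * self.pooled_se)

    @property
    def heterogeneous(self) -> bool:
        """Cochran's Q flag at p < 0.05."""
        return self.p_Q < 0.05

    def summary(self) -> str:
        lo, hi = self.ci
        return (f"{self.method} meta-analysis of k={self.k} studies\n"
                f"  pooled effect {self.pooled_effect:+.4f} "
                f"(SE {self.pooled_se:.4f}; 95% CI {lo:+.4f}, {hi:+.4f})\n"
                f"  Q = {self.Q:.3f} on {self.df} df (p = {self.p_Q:.3g}); "
                f"tau^2 = {self.tau2:.4f}")


def meta_analyse(effects, ses, method: str = "fixed") -> MetaResult:
    """Pool study effects by inverse-variance weighting.

    fixed: w_i = se_i^-2, pooled = sum(w b)/sum(w), se = sum(w)^-1/2.
    dersimonian_laird: tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)),
    then re-pool with w*_i = (se_i^2 + tau^2)^-1.
    """
    b = np.asarray(effects, float)
    s = np.asarray(ses, float)
    if b.size == 0:
        raise ValueError("no studies to pool")
    if b.shape != s.shape:
        raise ValueError("effects and ses must have equal length")
    if np.any(s <= 0):
        raise ValueError("all ses must be > 0")
    if method not in ("fixed", "dersimonian_laird"):
        raise ValueError(f"unknown method {method!r}")

    w = s ** -2.0
    pooled_fixed = float(w @ b / w.sum())
    k = b.size
    df = k - 1
    Q = float(w @ (b - pooled_fixed) ** 2)
    p_Q = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0

    if method == "fixed":
        return MetaResult(pooled_fixed, float(w.sum() ** -0.5), k, Q, df, p_Q,
                          0.0, "fixed")

    if df == 0:
        tau2 = 0.0
    else:
        c = w.sum() - (w ** 2).sum() / w.sum()
        tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (s ** 2 + tau2)
    pooled = float(w_star @ b / w_star.sum())
    return MetaResult(pooled, float(w_star.sum() ** -0.5), k, Q, df, p_Q,
                      tau2, "dersimonian_laird")


class MetaAnalysis:
    """Model-style front end: hold the study table, ``fit()`` pools it."""

    def __init__(self, effects, ses, labels=None):
        self.effects = np.asarray(effects, float)
        self.ses = np.asarray(ses, float)
        self.labels = list(labels) if labels is not None else \
            [f"study_{i}" for i in range(self.effects.size)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, effect_col: str = "effect",
                       se_col: str = "se", label_col: str | None = None):
        labels = df[label_col] if label_col else None
        return cls(df[effect_col], df[se_col], labels)

    def fit(self, method: str = "fixed") -> MetaResult:
        return meta_analyse(self.effects, self.ses, method=method)


def pool_per_snp(tables: list[AssociationTable],
                 method: str = "fixed") -> AssociationTable:
    """Meta-analyse cohort-specific SNP-outcome tables variant by variant.

    Tables must already share allele orientation (all scans emit genotypes
    on the BMI-increasing allele).  Each variant is pooled over the cohorts
    in which it appears; the per-variant number of cohorts is recorded in a
    ``k`` column.
    """
    if not tables:
        raise ValueError("no tables to pool")
    master: list[str] = []
    for t in tables:
        for vid in t.variant_ids:
            if vid not in master:
                master.append(vid)
    frames = {id(t): t.df.set_index("variant_id") for t in tables}
    rows = []
    for vid in master:
        betas, ses, ns, eafs = [], [], [], []
        ea = oa = None
        for t in tables:
            df = frames[id(t)]
            if vid in df.index:
                r = df.loc[vid]
                betas.append(float(r["beta"]))
                ses.append(float(r["se"]))
                ns.append(float(r["n"]))
                eafs.append(float(r["eaf"]))
                ea, oa = r["effect_allele"], r["other_allele"]
        if not betas:
            logger.info("pool_per_snp: %s present in no cohort, dropped", vid)
            continue
        res = meta_analyse(betas, ses, method=method)
        ns_arr = np.asarray(ns)
        rows.append({"variant_id": vid, "effect_allele": ea, "other_allele": oa,
                     "eaf": float(np.average(eafs, weights=ns_arr)),
                     "beta": res.pooled_effect, "se": res.pooled_se,
                     "n": float(ns_arr.sum()), "k": res.k,
                     "Q": res.Q, "p_Q": res.p_Q})
    trait = tables[0].trait
    return AssociationTable(pd.DataFrame(rows), trait=trait, sample="pooled")


def leave_one_out_pool(tables: list[AssociationTable], method: str = "fixed",
                       labels=None) -> list[tuple[str, AssociationTable]]:
    """Re-pool per-SNP tables omitting one cohort at a time."""
    if len(tables) < 2:
        raise ValueError("leave-one-out requires at least 2 cohorts")
    if labels is None:
        labels = [t.sample or f"cohort_{i}" for i, t in enumerate(tables)]
    out = []
    for i, label in enumerate(labels):
        rest = [t for j, t in enumerate(tables) if j != i]
        out.append((label, pool_per_snp(rest, method=method)))
    return out
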