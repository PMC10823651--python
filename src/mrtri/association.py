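"""Per-cohort analysis arms on individual-level trio data.

Three regression-based building blocks:

* multivariable regression of each outcome on maternal BMI (per within-
  cohort SD) under a minimal (maternal age + offspring sex) or full
  (+ education, parity, smoking, alcohol) adjustment set;
* per-SNP genotype-outcome scans under an additive model, optionally
  conditioning each maternal SNP on the offspring's genotype at the same
  SNP to close the transmission path;
* the paternal negative-control pair: paternal BMI adjusted for maternal
  BMI and paternal covariates, against the maternal estimate mutually
  adjusted for paternal BMI and paternal covariates.

Effects for binary outcomes are log odds ratios (exp() gives the OR);
continuous outcomes give SD-unit slopes.  All arms refuse outcomes with
fewer than 10 cases rather than returning unstable estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import fit_glm, fit_glm_grouped_binary
from .simulate import TrioCohort
from .summary import AssociationTable

logger = logging.getLogger(__name__)

MIN_CASES = 10
Z95 = stats.norm.ppf(0.975)

MINIMAL_ADJUSTMENT = ("age", "offspring_sex")
FULL_ADJUSTMENT = ("age", "offspring_sex", "education", "parity",
                   "smoking", "alcohol")
PATERNAL_ADJUSTMENT = ("age_p", "parity", "education_p", "smoking_p",
                       "alcohol_p", "offspring_sex")


@dataclass
class ArmEstimate:
    """One analysis arm's effect per SD of BMI, with Wald 95% CI."""

    outcome: str
    approach: str  # mvr_min | mvr_full | mvr_mutual | mr_ivw | mr_adjusted | paternal_nc
    effect: float  # log-OR (binary) or SD-unit slope (continuous)
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_cases: int | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.effect))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_row(self) -> dict:
        return {"outcome": self.outcome, "approach": self.approach,
                "effect": self.effect, "se": self.se, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n": self.n, "n_cases": self.n_cases}


def arm_estimates_to_tsv(estimates, path) -> None:
    pd.DataFrame([e.to_row() for e in estimates]).to_csv(
        path, sep="\t", index=False, float_format="%.8g")


def _outcome_kind(y: np.ndarray) -> str:
    return "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"


def _check_cases(y: np.ndarray, outcome: str, family: str) -> int | None:
    if family != "logistic":
        return None
    n_cases = int(y.sum())
    if min(n_cases, len(y) - n_cases) < MIN_CASES:
        raise ValueError(
            f"{outcome}: only {n_cases} cases / {len(y) - n_cases} controls; "
            f"refusing to fit with fewer than {MIN_CASES} in a cell")
    return n_cases


def _standardized_bmi(cohort: TrioCohort, column: str) -> np.ndarray:
    x = cohort.phenotypes[column].to_numpy(float)
    return (x - x.mean()) / x.std(ddof=1)


def _design(cohort: TrioCohort, columns) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(cohort.n_families)]
    names = ["intercept"]
    for c in columns:
        cols.append(cohort.phenotypes[c].to_numpy(float))
        names.append(c)
    return np.column_stack(cols), names


def _wald_arm(outcome, approach, est, se, n, n_cases) -> ArmEstimate:
    return ArmEstimate(outcome, approach, float(est), float(se),
                       float(est - Z95 * se), float(est + Z95 * se),
                       int(n), n_cases)


def mvr_estimate(cohort: TrioCohort, outcome: str,
                 adjustment: str = "full") -> ArmEstimate:
    """Multivariable-regression effect of maternal BMI per within-cohort SD."""
    if outcome not in cohort.outcomes.columns:
        raise KeyError(f"outcome {outcome!r} not in cohort")
    covs = {"minimal": MINIMAL_ADJUSTMENT, "full": FULL_ADJUSTMENT}[adjustment]
    y = cohort.outcomes[outcome].to_numpy(float)
    family = _outcome_kind(y)
    n_cases = _check_cases(y, outcome, family)
    X, names = _design(cohort, covs)
    bmi = _standardized_bmi(cohort, "bmi_m")
    X = np.column_stack([X[:, :1], bmi, X[:, 1:]])
    names = [names[0], "bmi_m"] + names[1:]
    res = fit_glm(y, X, family=family, names=names)
    return _wald_arm(outcome, f"mvr_{'full' if adjustment == 'full' else 'min'}",
                     res.params[1], res.bse[1], cohort.n_families, n_cases)


def _scan_binary_snp(y: np.ndarray, g: np.ndarray,
                     g_off: np.ndarray | None):
    """Grouped logistic fit of a 0/1/2 genotype (optionally + offspring SNP)."""
    if g_off is None:
        cells = g.astype(np.intp)  # 3 cells
        designs = np.column_stack([np.ones(3), np.arange(3.0)])
        n_cells = 3
    else:
        cells = (3 * g + g_off).astype(np.intp)  # 9 cells
        gm, go = np.divmod(np.arange(9), 3)
        designs = np.column_stack([np.ones(9), gm.astype(float), go.astype(float)])
        n_cells = 9
    idx = 2 * cells + y.astype(np.intp)
    counts = np.bincount(idx, minlength=2 * n_cells).reshape(n_cells, 2)
    res = fit_glm_grouped_binary(counts, designs,
                                 names=["intercept", "g_m", "g_off"][:designs.shape[1]])
    return res.params[1], res.bse[1]


def snp_outcome_scan(cohort: TrioCohort, outcome: str,
                     adjust_offspring: bool = False) -> AssociationTable:
    """Per-SNP additive regression of an outcome on maternal genotype.

    With ``adjust_offspring`` the offspring genotype at the same SNP enters
    as a covariate, blocking the inherited-allele path.  Monomorphic SNPs
    are dropped with a log entry.  Effect alleles are the BMI-increasing
    alleles the genotypes are counted on.
    """
    if outcome not in cohort.outcomes.columns:
        raise KeyError(f"outcome {outcome!r} not in cohort")
    y = cohort.outcomes[outcome].to_numpy(float)
    family = _outcome_kind(y)
    if family == "logistic":
        _check_cases(y, outcome, family)
    rows, dropped = [], 0
    n = cohort.n_families
    for j, vid in enumerate(cohort.snp_ids):
        g = cohort.maternal_genotypes[:, j].astype(float)
        if g.min() == g.max():
            dropped += 1
            continue
        g_off = cohort.offspring_genotypes[:, j].astype(float) \
            if adjust_offspring else None
        if family == "logistic":
            beta, se = _scan_binary_snp(y, g, g_off)
        else:
            cols = [np.ones(n), g] + ([g_off] if g_off is not None else [])
            res = fit_glm(y, np.column_stack(cols), family="linear",
                          names=["intercept", "g_m", "g_off"][:len(cols)])
            beta, se = res.params[1], res.bse[1]
        rows.append({"variant_id": vid, "effect_allele": "A",
                     "other_allele": "G", "eaf": float(g.mean() / 2.0),
                     "beta": float(beta), "se": float(se), "n": n})
    if dropped:
        logger.info("snp_outcome_scan(%s): dropped %d monomorphic SNPs",
                    outcome, dropped)
    if not rows:
        raise ValueError(f"{outcome}: no polymorphic SNPs to scan")
    label = "adjusted" if adjust_offspring else "unadjusted"
    return AssociationTable(pd.DataFrame(rows), trait=outcome,
                            sample=f"{cohort.cohort_id}:{label}")


def paternal_negative_control(cohort: TrioCohort, outcome: str
                              ) -> tuple[ArmEstimate, ArmEstimate]:
    """Mutually adjusted maternal estimate and paternal negative control.

    Paternal arm: paternal BMI (per SD) adjusted for maternal BMI, paternal
    age/education/smoking/alcohol, number of children, and offspring sex.
    Maternal arm: maternal BMI additionally adjusted for paternal BMI and
    the paternal confounders (on top of the full maternal set).
    Returns (maternal_mutual, paternal_nc).
    """
    if "bmi_p" not in cohort.phenotypes.columns:
        raise KeyError("paternal BMI absent from cohort")
    y = cohort.outcomes[outcome].to_numpy(float)
    family = _outcome_kind(y)
    n_cases = _check_cases(y, outcome, family)
    bmi_m = _standardized_bmi(cohort, "bmi_m")
    bmi_p = _standardized_bmi(cohort, "bmi_p")

    Xp, names_p = _design(cohort, PATERNAL_ADJUSTMENT)
    Xp = np.column_stack([Xp[:, :1], bmi_p, bmi_m, Xp[:, 1:]])
    names_p = ["intercept", "bmi_p", "bmi_m"] + names_p[1:]
    res_p = fit_glm(y, Xp, family=family, names=names_p)
    paternal = _wald_arm(outcome, "paternal_nc", res_p.params[1], res_p.bse[1],
                         cohort.n_families, n_cases)

    mutual_covs = tuple(dict.fromkeys(FULL_ADJUSTMENT + PATERNAL_ADJUSTMENT))
    Xm, names_m = _design(cohort, mutual_covs)
    Xm = np.column_stack([Xm[:, :1], bmi_m, bmi_p, Xm[:, 1:]])
    names_m = ["intercept", "bmi_m", "bmi_p"] + names_m[1:]
    res_m = fit_glm(y, Xm, family=family, names=names_m)
    maternal = _wald_arm(outcome, "mvr_mutual", res_m.params[1], res_m.bse[1],
                         cohort.n_families, n_cases)
    return maternal, paternal
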