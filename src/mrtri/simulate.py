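"""Mother-father-offspring cohort simulator and reference-GWAS generator.

The generator encodes the bias structures the three triangulation arms are
designed to disentangle:

* a polygenic maternal BMI built from independent biallelic SNPs coded on
  the BMI-increasing allele (Hardy-Weinberg genotypes, Mendelian
  transmission to the offspring);
* an unmeasured confounder ``U`` affecting both maternal BMI and outcomes
  (the residual-confounding threat to multivariable regression);
* a shared couple factor ``S`` loading on both parents' BMI, reproducing
  the spousal BMI correlation that the paternal negative-control design
  exploits (assortative mating / shared lifestyle as a phenotypic factor;
  spousal genotypes stay independent);
* per-SNP horizontal pleiotropy (direct SNP-outcome effects), the threat to
  Mendelian randomisation probed by the Egger intercept;
* a direct effect of the *offspring's* inherited allele score on perinatal
  outcomes, the transmission path closed by offspring-genotype adjustment.

Maternal BMI is standardized:  bmi_m = sum_j a_j (g_mj - 2 f_j)
+ lam_U * U + lam_S * S + sum_k c_k z_k + eps,  with the loadings' squared
sum plus the genetic variance 2 sum_j f_j (1-f_j) a_j^2 constrained below 1
and eps absorbing the remainder.  Binary outcomes are Bernoulli draws from
a logistic model whose intercept is calibrated by root finding to hit a
target prevalence exactly on the simulated linear predictor.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .summary import AssociationTable

#: Maternal/paternal covariate distributions (means/rates match typical
#: pregnancy-cohort descriptives: maternal age ~30 (SD 4.7) years).
COVARIATE_DISTRIBUTIONS = {
    "age": ("normal", 30.0, 4.7),
    "parity": ("poisson", 0.8),
    "education": ("ordinal", (0.2, 0.3, 0.3, 0.2)),  # levels 0..3
    "smoking": ("bernoulli", 0.2),
    "alcohol": ("bernoulli", 0.3),
    "offspring_sex": ("bernoulli", 0.5),
}

MATERNAL_COVARIATES = ("age", "parity", "education", "smoking", "alcohol")
PATERNAL_COVARIATES = ("age_p", "education_p", "smoking_p", "alcohol_p")


@dataclass
class OutcomeSpec:
    """Causal structure of one simulated outcome.

    Effects are log odds ratios for binary outcomes and SD units for
    continuous ones; ``maternal_effect`` / ``paternal_effect`` are per SD of
    parental BMI, ``offspring_score_effect`` per unit of the offspring's
    centred weighted allele score, ``pleiotropy_mean``/``sd`` parametrise
    per-SNP direct effects on the outcome.
    """

    name: str
    kind: str = "binary"  # "binary" | "continuous"
    prevalence: float | None = 0.05
    maternal_effect: float = 0.0
    paternal_effect: float = 0.0
    confounder_effect: float = 0.0
    couple_effect: float = 0.0
    offspring_score_effect: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    covariate_effects: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"{self.name}: kind must be binary or continuous")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ValueError(f"{self.name}: prevalence must be in (0,1)")
            if not np.isfinite(self.prevalence):
                raise ValueError(f"{self.name}: non-finite prevalence")


@dataclass
class SimulationConfig:
    """Everything that determines a simulated multi-cohort study.

    The seed fully determines the output; cohorts get independent child
    seeds, while SNP parameters (frequencies, effects, pleiotropy) are drawn
    once per configuration so that all cohorts share the same variants.
    """

    n_families: int = 10_000
    n_snps: int = 97
    seed: int = 0
    allele_freqs: np.ndarray | None = None
    snp_effects: np.ndarray | None = None
    total_r2: float = 0.027  # BMI variance explained by the instruments
    confounder_loading_bmi: float = 0.0  # lam_U
    couple_loading: float = 0.0          # lam_S
    covariate_loadings_bmi: dict = field(default_factory=dict)
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    n_cohorts: int = 1
    cohort_sizes: list[int] | None = None  # overrides n_families per cohort

    def __post_init__(self):
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 977]))
        if self.allele_freqs is None:
            self.allele_freqs = rng.uniform(0.1, 0.9, self.n_snps)
        self.allele_freqs = np.asarray(self.allele_freqs, float)
        self.n_snps = len(self.allele_freqs)
        if self.snp_effects is None:
            raw = np.abs(rng.normal(size=self.n_snps))
            var = 2.0 * self.allele_freqs * (1 - self.allele_freqs)
            raw *= np.sqrt(self.total_r2 / np.sum(var * raw ** 2))
            self.snp_effects = raw
        self.snp_effects = np.asarray(self.snp_effects, float)
        self.validate()

    @property
    def genetic_variance(self) -> float:
        f = self.allele_freqs
        return float(np.sum(2 * f * (1 - f) * self.snp_effects ** 2))

    @property
    def residual_sd(self) -> float:
        loads = (self.genetic_variance
                 + self.confounder_loading_bmi ** 2
                 + self.couple_loading ** 2
                 + sum(v ** 2 for v in self.covariate_loadings_bmi.values()))
        if loads >= 1.0:
            raise ValueError(
                f"BMI variance components sum to {loads:.3f} >= 1; "
                "reduce SNP effects or loadings")
        return float(np.sqrt(1.0 - loads))

    def validate(self) -> None:
        if np.any((self.allele_freqs <= 0) | (self.allele_freqs >= 1)):
            raise ValueError("allele frequencies must be in (0,1)")
        if len(self.snp_effects) != self.n_snps:
            raise ValueError("snp_effects length mismatch")
        _ = self.residual_sd  # raises if variance budget exceeded
        for spec in self.outcomes:
            spec.validate()
        unknown = set(self.covariate_loadings_bmi) - set(MATERNAL_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in BMI loadings: {unknown}")

    @property
    def snp_ids(self) -> list[str]:
        return [f"rs{1000 + j}" for j in range(self.n_snps)]

    def pleiotropy_effects(self, outcome: OutcomeSpec) -> np.ndarray:
        """Per-SNP direct outcome effects, fixed per (config, outcome)."""
        if outcome.pleiotropy_mean == 0.0 and outcome.pleiotropy_sd == 0.0:
            return np.zeros(self.n_snps)
        key = zlib.crc32(outcome.name.encode()) % (2 ** 31)
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 313, key]))
        return rng.normal(outcome.pleiotropy_mean, outcome.pleiotropy_sd, self.n_snps)


@dataclass
class TrioCohort:
    """One simulated cohort of mother-father-offspring trios."""

    cohort_id: str
    snp_ids: list[str]
    allele_freqs: np.ndarray
    snp_effects: np.ndarray
    maternal_genotypes: np.ndarray  # families x SNPs, int8, BMI-increasing allele counts
    paternal_genotypes: np.ndarray
    offspring_genotypes: np.ndarray
    phenotypes: pd.DataFrame  # bmi_m, bmi_p + covariates
    outcomes: pd.DataFrame
    oracle: pd.DataFrame  # U_m, U_p, S: for generator checks only, never analysed

    @property
    def n_families(self) -> int:
        return len(self.phenotypes)

    def allele_score(self, who: str = "offspring") -> np.ndarray:
        """Centred weighted allele score for mother/father/offspring."""
        g = {"maternal": self.maternal_genotypes,
             "paternal": self.paternal_genotypes,
             "offspring": self.offspring_genotypes}[who]
        return (g - 2 * self.allele_freqs) @ self.snp_effects

    def to_tsv(self, directory, genotypes: bool = True) -> None:
        """Write one row per family plus a JSON sidecar with provenance."""
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        tab = pd.concat([self.phenotypes, self.outcomes], axis=1)
        tab.insert(0, "family_id", np.arange(len(tab)))
        tab.to_csv(d / f"{self.cohort_id}_families.tsv", sep="\t",
                   index=False, float_format="%.8g")
        if genotypes:
            for who, g in (("maternal", self.maternal_genotypes),
                           ("paternal", self.paternal_genotypes),
                           ("offspring", self.offspring_genotypes)):
                gdf = pd.DataFrame(g, columns=self.snp_ids)
                gdf.to_csv(d / f"{self.cohort_id}_{who}_genotypes.tsv",
                           sep="\t", index=False)
        sidecar = {
            "cohort_id": self.cohort_id,
            "n_families": self.n_families,
            "snp_ids": self.snp_ids,
            "allele_freqs": [float(x) for x in self.allele_freqs],
            "snp_effects": [float(x) for x in self.snp_effects],
        }
        (d / f"{self.cohort_id}_meta.json").write_text(json.dumps(sidecar, indent=1))


def calibrate_intercept(linear_predictor, target_prevalence: float) -> float:
    """Intercept b0 such that mean(expit(b0 + lp)) == target prevalence.

    One-dimensional root finding (Brent); the mean risk is monotone in b0 so
    the root is unique.  Raises if the target is outside (0,1) or the linear
    predictor is non-finite.
    """
    lp = np.asarray(linear_predictor, float)
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target prevalence must be in (0,1)")
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")

    def f(b0):
        return float(np.mean(expit(b0 + lp))) - target_prevalence

    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("intercept root not bracketable")
    return float(brentq(f, lo, hi, xtol=1e-10))


def couple_loading_for_correlation(rho: float) -> float:
    """Couple-factor loading lam_S giving corr(bmi_m, bmi_p) = rho.

    Both parents load lam_S on the shared standard-normal couple factor and
    have unit-variance BMI, so the correlation equals lam_S squared.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("correlation must be in [0,1)")
    return float(np.sqrt(rho))


def _draw_covariates(rng: np.random.Generator, n: int, paternal: bool = False):
    """Raw covariates and their standardized versions (theoretical moments)."""
    raw, z = {}, {}
    suffix = "_p" if paternal else ""
    for name, spec in COVARIATE_DISTRIBUTIONS.items():
        if paternal and name in ("parity", "offspring_sex"):
            continue  # couple-level, drawn once on the maternal side
        kind = spec[0]
        if kind == "normal":
            mean, sd = spec[1], spec[2]
            x = rng.normal(mean, sd, n)
            raw[name + suffix] = x
            z[name + suffix] = (x - mean) / sd
        elif kind == "poisson":
            lam = spec[1]
            x = rng.poisson(lam, n).astype(float)
            raw[name + suffix] = x
            z[name + suffix] = (x - lam) / np.sqrt(lam)
        elif kind == "bernoulli":
            p = spec[1]
            x = rng.binomial(1, p, n).astype(float)
            raw[name + suffix] = x
            z[name + suffix] = (x - p) / np.sqrt(p * (1 - p))
        elif kind == "ordinal":
            probs = np.asarray(spec[1])
            levels = np.arange(len(probs), dtype=float)
            x = rng.choice(levels, size=n, p=probs)
            mean = float(levels @ probs)
            sd = float(np.sqrt((levels - mean) ** 2 @ probs))
            raw[name + suffix] = x
            z[name + suffix] = (x - mean) / sd
    return raw, z


def _hwe_genotypes(rng: np.random.Generator, f: np.ndarray, n: int) -> np.ndarray:
    """Binomial(2, f) per SNP via two uniform comparisons (fast at scale)."""
    k = f.size
    g = (rng.random((n, k)) < f).astype(np.int8)
    g += rng.random((n, k)) < f
    return g


def _transmit(rng: np.random.Generator, parent_genotypes: np.ndarray) -> np.ndarray:
    """One Mendelian allele per parent: Binomial(1, g/2) at each SNP."""
    return (rng.random(parent_genotypes.shape)
            < parent_genotypes / 2.0).astype(np.int8)


def simulate_trio_cohort(config: SimulationConfig, cohort_id: str = "cohort_0",
                         cohort_index: int = 0,
                         n_families: int | None = None) -> TrioCohort:
    """Generate one trio cohort under the configured causal structure."""
    config.validate()
    n = int(n_families if n_families is not None else config.n_families)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(cohort_index)]))
    f = config.allele_freqs
    alpha = config.snp_effects
    k = config.n_snps

    g_m = _hwe_genotypes(rng, f, n)
    g_p = _hwe_genotypes(rng, f, n)
    g_o = (_transmit(rng, g_m) + _transmit(rng, g_p)).astype(np.int8)

    U_m = rng.normal(size=n)
    U_p = rng.normal(size=n)
    S = rng.normal(size=n)

    raw_m, z_m = _draw_covariates(rng, n)
    raw_p, z_p = _draw_covariates(rng, n, paternal=True)

    sd_eps = config.residual_sd
    lam_U = config.confounder_loading_bmi
    lam_S = config.couple_loading
    cov_part_m = sum(c * z_m[name] for name, c in config.covariate_loadings_bmi.items())
    cov_part_p = sum(c * z_p[name + "_p"]
                     for name, c in config.covariate_loadings_bmi.items()
                     if name + "_p" in z_p)
    G_m = (g_m - 2 * f) @ alpha
    G_p = (g_p - 2 * f) @ alpha
    bmi_m = G_m + lam_U * U_m + lam_S * S + cov_part_m + sd_eps * rng.normal(size=n)
    bmi_p = G_p + lam_U * U_p + lam_S * S + cov_part_p + sd_eps * rng.normal(size=n)

    score_off = (g_o - 2 * f) @ alpha

    z_all = {**z_m, **z_p}
    outcome_cols = {}
    for spec in config.outcomes:
        pi = config.pleiotropy_effects(spec)
        lp = (spec.maternal_effect * bmi_m
              + spec.paternal_effect * bmi_p
              + spec.confounder_effect * U_m
              + spec.couple_effect * S
              + spec.offspring_score_effect * score_off)
        if np.any(pi != 0):
            lp = lp + (g_m - 2 * f) @ pi
        for name, c in spec.covariate_effects.items():
            if name not in z_all:
                raise ValueError(f"{spec.name}: unknown covariate {name!r}")
            lp = lp + c * z_all[name]
        if spec.kind == "binary":
            b0 = calibrate_intercept(lp, spec.prevalence)
            outcome_cols[spec.name] = rng.binomial(
                1, expit(b0 + lp)).astype(np.int8)
        else:
            outcome_cols[spec.name] = lp + rng.normal(size=n)

    phen = pd.DataFrame({"bmi_m": bmi_m, "bmi_p": bmi_p, **raw_m, **raw_p})
    outcomes = pd.DataFrame(outcome_cols, index=phen.index) if outcome_cols \
        else pd.DataFrame(index=phen.index)
    oracle = pd.DataFrame({"U_m": U_m, "U_p": U_p, "S": S})
    return TrioCohort(cohort_id, config.snp_ids, f.copy(), alpha.copy(),
                      g_m, g_p, g_o, phen, outcomes, oracle)


def simulate_study(config: SimulationConfig) -> list[TrioCohort]:
    """Simulate all cohorts of a multi-cohort study."""
    sizes = config.cohort_sizes or [config.n_families] * config.n_cohorts
    return [simulate_trio_cohort(config, cohort_id=f"cohort_{i}", cohort_index=i,
                                 n_families=sz)
            for i, sz in enumerate(sizes)]


def simulate_reference_gwas(config: SimulationConfig, n_ref: int,
                            seed: int | None = None) -> AssociationTable:
    """Summary statistics of an independent exposure GWAS.

    Per SNP, beta-hat ~ Normal(alpha_j, se_j) with
    se_j = 1 / sqrt(2 f_j (1 - f_j) n_ref) (standardized-trait
    approximation).  Sampling is independent of every trio cohort, giving
    the two-sample structure.
    """
    if n_ref <= 0:
        raise ValueError("n_ref must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed if seed is None else seed), 171_977]))
    f = config.allele_freqs
    se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_ref)
    beta = rng.normal(config.snp_effects, se)
    df = pd.DataFrame({
        "variant_id": config.snp_ids,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": f,
        "beta": beta,
        "se": se,
        "n": n_ref,
    })
    return AssociationTable(df, trait="bmi", sample="reference_gwas")


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["allele_freqs"] = [float(x) for x in config.allele_freqs]
    d["snp_effects"] = [float(x) for x in config.snp_effects]
    return d
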