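"""Canonical simulation scenarios for parameter-recovery studies.

Each builder fixes the study conditions of one recovery experiment — sample
sizes, prevalences, instrument strength, confounding structure, and the
true effect the analysis should recover — so that tests, scripts and
documentation all run the same experiment.  The true effects are set to the
published point estimates for gestational hypertension, making recovery a
direct check that each analysis arm measures what it claims to measure.
"""

from __future__ import annotations

import numpy as np

from .simulate import (OutcomeSpec, SimulationConfig,
                       couple_loading_for_correlation)

#: Published estimates used as simulation truths (gestational hypertension).
GH_MVR_OR = 1.67       # multivariable regression, fully adjusted
GH_MR_OR = 1.59        # two-sample MR (IVW)
GH_PREVALENCE = 0.0416
SPOUSAL_BMI_CORRELATION = 0.24  # largest negative-control cohort
REFERENCE_GWAS_N = 171_977
INSTRUMENT_TOTAL_R2 = 0.027
N_INSTRUMENTS = 97

#: Measured-confounder structure: loadings of standardized covariates on
#: maternal BMI (SD units) and their direct log-OR effects on the outcome.
COVARIATE_BMI_LOADINGS = {"age": 0.15, "education": 0.10, "smoking": 0.10,
                          "alcohol": 0.05, "parity": 0.10}
COVARIATE_OUTCOME_EFFECTS = {"age": 0.15, "education": -0.10, "smoking": 0.25,
                             "alcohol": 0.05, "parity": 0.10,
                             "offspring_sex": 0.05}


def gh_outcome(maternal_effect: float = float(np.log(GH_MVR_OR)),
               **overrides) -> OutcomeSpec:
    kwargs = dict(name="gestational_hypertension", kind="binary",
                  prevalence=GH_PREVALENCE, maternal_effect=maternal_effect,
                  covariate_effects=dict(COVARIATE_OUTCOME_EFFECTS))
    kwargs.update(overrides)
    return OutcomeSpec(**kwargs)


def mvr_recovery_config(n_families: int = 200_000, seed: int = 0) -> SimulationConfig:
    """Fully measured confounding; true conditional log-OR = log(1.67)."""
    return SimulationConfig(
        n_families=n_families, n_snps=N_INSTRUMENTS, seed=seed,
        total_r2=INSTRUMENT_TOTAL_R2,
        covariate_loadings_bmi=dict(COVARIATE_BMI_LOADINGS),
        outcomes=[gh_outcome()])


def mr_recovery_config(n_families: int = 400_000, seed: int = 0) -> SimulationConfig:
    """Valid-instrument two-sample MR; true causal log-OR = log(1.59)."""
    return SimulationConfig(
        n_families=n_families, n_snps=N_INSTRUMENTS, seed=seed,
        total_r2=INSTRUMENT_TOTAL_R2,
        outcomes=[gh_outcome(maternal_effect=float(np.log(GH_MR_OR)),
                             covariate_effects={})])


def paternal_nc_config(n_families: int = 100_000, seed: int = 0,
                       spousal_correlation: float = 0.2,
                       couple_effect: float = 0.05) -> SimulationConfig:
    """Zero direct paternal effect; shared couple factor loading weakly on
    the outcome (residual shared-environment confounding)."""
    return SimulationConfig(
        n_families=n_families, n_snps=N_INSTRUMENTS, seed=seed,
        total_r2=INSTRUMENT_TOTAL_R2,
        couple_loading=couple_loading_for_correlation(spousal_correlation),
        covariate_loadings_bmi=dict(COVARIATE_BMI_LOADINGS),
        outcomes=[gh_outcome(couple_effect=couple_effect)])


def spousal_correlation_config(n_families: int = 50_000, seed: int = 0,
                               rho: float = SPOUSAL_BMI_CORRELATION
                               ) -> SimulationConfig:
    """Couple-factor loading calibrated to the spousal BMI correlation."""
    return SimulationConfig(
        n_families=n_families, n_snps=20, seed=seed, total_r2=INSTRUMENT_TOTAL_R2,
        couple_loading=couple_loading_for_correlation(rho), outcomes=[])
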