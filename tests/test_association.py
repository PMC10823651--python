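"""Regression arms on simulated cohorts: recovery, bias structure, scans."""

import numpy as np
import pytest
from scipy import stats

from mrtri.association import (mvr_estimate, paternal_negative_control,
                               snp_outcome_scan)
from mrtri.mr import mr_ivw
from mrtri.simulate import (OutcomeSpec, SimulationConfig,
                            couple_loading_for_correlation,
                            simulate_reference_gwas, simulate_trio_cohort)
from mrtri.summary import harmonised_frame


def cohort_with(outcomes, n=30_000, seed=5, **cfg_kwargs):
    defaults = dict(n_families=n, n_snps=10, seed=seed, total_r2=0.05)
    defaults.update(cfg_kwargs)
    return simulate_trio_cohort(SimulationConfig(outcomes=outcomes, **defaults))


class TestMvrEstimate:
    def test_linear_slope_recovery_continuous_outcome(self):
        c = cohort_with([OutcomeSpec("birthweight", "continuous", None,
                                     maternal_effect=0.25)])
        arm = mvr_estimate(c, "birthweight", adjustment="full")
        assert arm.effect == pytest.approx(0.25, abs=4 * arm.se)
        assert arm.ci_low < arm.effect < arm.ci_high

    def test_omitted_confounder_biases_minimal_model(self):
        # smoking raises BMI and the outcome; only the full model adjusts it
        c = cohort_with(
            [OutcomeSpec("preterm_birth", "binary", 0.15,
                         covariate_effects={"smoking": 0.8})],
            covariate_loadings_bmi={"smoking": 0.4})
        minimal = mvr_estimate(c, "preterm_birth", adjustment="minimal")
        full = mvr_estimate(c, "preterm_birth", adjustment="full")
        assert abs(full.effect) < 4 * full.se  # truth is null
        assert minimal.effect > full.effect + 0.05  # positive confounding

    def test_few_cases_refused(self):
        c = cohort_with([OutcomeSpec("stillbirth_index", "binary", 1e-4)],
                        n=5_000)
        with pytest.raises(ValueError, match="cases"):
            mvr_estimate(c, "stillbirth_index")

    def test_unknown_outcome_rejected(self):
        c = cohort_with([])
        with pytest.raises(KeyError):
            mvr_estimate(c, "not_there")

    def test_standardization_equivalence_linear(self):
        # fitting on standardized BMI equals raw-BMI slope times the SD
        from mrtri.glm import fit_glm
        c = cohort_with([OutcomeSpec("birthweight", "continuous", None,
                                     maternal_effect=0.3)], n=5_000)
        y = c.outcomes["birthweight"].to_numpy()
        bmi = c.phenotypes["bmi_m"].to_numpy()
        sd = bmi.std(ddof=1)
        X_raw = np.column_stack([np.ones(len(y)), bmi])
        raw = fit_glm(y, X_raw, family="linear")
        X_std = np.column_stack([np.ones(len(y)), (bmi - bmi.mean()) / sd])
        std = fit_glm(y, X_std, family="linear")
        assert std.params[1] == pytest.approx(raw.params[1] * sd, rel=1e-10)


class TestSnpScan:
    def test_chain_rule_recovers_theta_times_alpha(self):
        theta = 0.4
        c = cohort_with([OutcomeSpec("caesarean_section", "binary", 0.2,
                                     maternal_effect=theta)], n=50_000)
        scan = snp_outcome_scan(c, "caesarean_section")
        # pooled across SNPs through IVW with the true effects as exposure
        exposure = simulate_reference_gwas(
            SimulationConfig(n_families=1, n_snps=10, seed=5, total_r2=0.05),
            10 ** 9)
        fit = mr_ivw(harmonised_frame(exposure, scan))
        assert fit.estimate == pytest.approx(theta, abs=4 * fit.se)

    def test_offspring_adjustment_closes_transmission_path(self):
        c = cohort_with(
            [OutcomeSpec("nicu_admission", "binary", 0.2,
                         offspring_score_effect=1.0)],
            n=30_000, total_r2=0.1)
        exposure = simulate_reference_gwas(
            SimulationConfig(n_families=1, n_snps=10, seed=5, total_r2=0.1),
            10 ** 9)
        unadj = mr_ivw(harmonised_frame(
            exposure, snp_outcome_scan(c, "nicu_admission")))
        adj = mr_ivw(harmonised_frame(
            exposure, snp_outcome_scan(c, "nicu_admission",
                                       adjust_offspring=True)))
        # inherited-allele path: unadjusted IVW sees ~ delta/2, adjusted ~ 0
        assert unadj.estimate > 0.25
        assert abs(adj.estimate) < 4 * adj.se

    def test_effect_allele_and_eaf_recorded(self):
        c = cohort_with([OutcomeSpec("preterm_birth", "binary", 0.2)],
                        n=5_000)
        scan = snp_outcome_scan(c, "preterm_birth")
        assert set(scan.df["effect_allele"]) == {"A"}
        np.testing.assert_allclose(scan.df["eaf"],
                                   c.maternal_genotypes.mean(axis=0) / 2)

    def test_constant_outcome_errors(self):
        c = cohort_with([OutcomeSpec("preterm_birth", "binary", 0.2)],
                        n=2_000)
        c.outcomes["preterm_birth"] = 0
        with pytest.raises(ValueError):
            snp_outcome_scan(c, "preterm_birth")

    def test_permuted_outcome_gives_uniform_p_values(self):
        c = cohort_with([OutcomeSpec("induction_of_labour", "binary", 0.3)],
                        n=4_000, n_snps=97, total_r2=0.027, seed=3)
        rng = np.random.default_rng(99)
        c.outcomes["induction_of_labour"] = rng.permutation(
            c.outcomes["induction_of_labour"].to_numpy())
        scan = snp_outcome_scan(c, "induction_of_labour")
        assert stats.kstest(scan.df["p"], "uniform").pvalue > 0.01


class TestPaternalNegativeControl:
    def test_shared_couple_confounding_isolated_to_maternal_truth(self):
        theta_m = np.log(1.67)
        c = cohort_with(
            [OutcomeSpec("gestational_hypertension", "binary", 0.06,
                         maternal_effect=theta_m, couple_effect=0.05)],
            n=60_000, couple_loading=couple_loading_for_correlation(0.2))
        maternal, paternal = paternal_negative_control(
            c, "gestational_hypertension")
        assert paternal.odds_ratio == pytest.approx(1.01, abs=0.05)
        assert maternal.ci_low > np.log(1.4)

    def test_shared_unmeasured_confounder_biases_both_arms_alike(self):
        # couple factor drives both BMIs and the outcome; neither parent has
        # a causal effect, so similar elevated estimates flag the bias
        c = cohort_with(
            [OutcomeSpec("gestational_diabetes", "binary", 0.1,
                         couple_effect=0.5)],
            n=50_000, couple_loading=0.6)
        maternal, paternal = paternal_negative_control(c,
                                                       "gestational_diabetes")
        assert maternal.ci_low > 0 and paternal.ci_low > 0
        assert maternal.effect == pytest.approx(
            paternal.effect, abs=3 * (maternal.se + paternal.se))

    def test_no_couple_factor_mutual_adjustment_changes_little(self):
        c = cohort_with(
            [OutcomeSpec("preeclampsia", "binary", 0.1,
                         maternal_effect=0.4)],
            n=40_000, couple_loading=0.0)
        r = np.corrcoef(c.phenotypes["bmi_m"], c.phenotypes["bmi_p"])[0, 1]
        assert abs(r) < 0.03
        maternal, _ = paternal_negative_control(c, "preeclampsia")
        plain = mvr_estimate(c, "preeclampsia", adjustment="full")
        assert maternal.effect == pytest.approx(plain.effect, abs=0.03)
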