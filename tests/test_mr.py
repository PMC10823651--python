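"""Two-sample MR estimators: oracles, invariances, robustness, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mrtri.mr import (TwoSampleMR, mr_egger, mr_heterogeneity, mr_ivw,
                      mr_leave_one_study_out, mr_weighted_median,
                      mr_weighted_mode, wald_ratio,
                      _weighted_median_estimate, _mode_bandwidth)
from mrtri.summary import AssociationTable

from conftest import make_table


def frame(bx, sx, by, sy):
    return pd.DataFrame({"bx": bx, "sx": sx, "by": by, "sy": sy})


def simulate_summary(rng, k=97, theta=0.0, r2_total=0.027, n_ref=171_977,
                     n_out=400_000, prevalence=0.04, pleiotropy=None,
                     alpha_dist="halfnormal"):
    """Summary-level two-sample data with valid or pleiotropic instruments.

    ``alpha_dist='lognormal'`` gives heavy-tailed, sign-certain effect sizes
    (a realistic profile for genome-wide-significant hits) with enough
    between-instrument spread for Egger regression; the half-normal default
    allows near-null instruments.
    """
    f = rng.uniform(0.1, 0.9, k)
    var = 2 * f * (1 - f)
    if alpha_dist == "lognormal":
        alpha = rng.lognormal(0.0, 0.7, k)
    else:
        alpha = np.abs(rng.normal(size=k))
    alpha *= np.sqrt(r2_total / np.sum(var * alpha ** 2))
    sx = 1 / np.sqrt(var * n_ref)
    bx = rng.normal(alpha, sx)
    sy = 1 / np.sqrt(var * n_out * prevalence * (1 - prevalence))
    mean_by = theta * alpha
    if pleiotropy is not None:
        mean_by = mean_by + pleiotropy
    by = rng.normal(mean_by, sy)
    return frame(bx, sx, by, sy), alpha


class TestWaldRatio:
    def test_arithmetic(self):
        assert wald_ratio(1.0, 0.1, 0.5, 0.1) == pytest.approx((0.5, 0.1))
        assert wald_ratio(0.05, 0.01, 0.023, 0.01) == pytest.approx((0.46, 0.2))
        assert wald_ratio(0.3, 0.1, 0.0, 0.1)[0] == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.1, 0.5, 0.1)


class TestIVW:
    def test_single_snp_degrades_to_wald(self):
        with pytest.warns(UserWarning, match="single instrument"):
            fit = mr_ivw(frame([0.5], [0.05], [0.25], [0.1]))
        assert fit.method == "wald"
        assert fit.estimate == pytest.approx(0.5)
        assert fit.se == pytest.approx(0.2)

    def test_two_snp_symmetry(self):
        fit = mr_ivw(frame([1.0, 1.0], [0.1, 0.1], [0.4, 0.6], [1.0, 1.0]))
        assert fit.estimate == pytest.approx(0.5)

    def test_matches_statsmodels_wls_through_origin(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        data, _ = simulate_summary(rng, k=30, theta=0.3)
        fit = mr_ivw(data)
        w = data["sy"].to_numpy() ** -2.0
        ref = sm.WLS(data["by"], data[["bx"]], weights=w).fit()
        assert fit.estimate == pytest.approx(ref.params.iloc[0], abs=1e-10)
        # multiplicative random effects reproduce the WLS residual scaling
        fit_mre = mr_ivw(data, effects_model="multiplicative_random")
        if fit.Q / (fit.n_snps - 1) >= 1:
            assert fit_mre.se == pytest.approx(ref.bse.iloc[0], rel=1e-6)

    def test_q_zero_on_exact_line(self):
        bx = np.array([0.2, 0.5, 0.9])
        fit = mr_ivw(frame(bx, [0.01] * 3, 0.4 * bx, [0.1] * 3))
        assert fit.estimate == pytest.approx(0.4, abs=1e-12)
        assert fit.Q == pytest.approx(0.0, abs=1e-20)


class TestEgger:
    def test_exact_line_recovery(self):
        bx = np.array([0.1, 0.3, 0.5, 0.8])
        by = 0.05 + 0.3 * bx
        fit = mr_egger(frame(bx, [0.01] * 4, by, [0.1] * 4))
        assert fit.egger_intercept == pytest.approx(0.05, abs=1e-10)
        assert fit.estimate == pytest.approx(0.3, abs=1e-10)

    def test_reorientation_invariance(self, rng):
        data, _ = simulate_summary(rng, k=20, theta=0.3)
        flipped = data.copy()
        sel = rng.random(20) < 0.5
        flipped.loc[sel, "bx"] *= -1
        flipped.loc[sel, "by"] *= -1
        a, b = mr_egger(data), mr_egger(flipped)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, abs=1e-12)

    def test_no_spread_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            mr_egger(frame([0.2] * 4, [0.01] * 4, [0.1] * 4, [0.1] * 4))

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(frame([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.1] * 2))

    def test_matches_statsmodels_wls_with_intercept(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        data, _ = simulate_summary(rng, k=40, theta=0.4)
        data["bx"] = np.abs(data["bx"])
        fit = mr_egger(data)
        X = sm.add_constant(data["bx"])
        ref = sm.WLS(data["by"], X, weights=data["sy"] ** -2.0).fit()
        assert fit.estimate == pytest.approx(ref.params.iloc[1], abs=1e-10)
        assert fit.egger_intercept == pytest.approx(ref.params.iloc[0],
                                                    abs=1e-10)

    def test_intercept_recovers_directional_pleiotropy(self, rng):
        # InSIDE holds: pleiotropy drawn independently of instrument strength
        mu_pi = 0.02
        intercepts, slopes, ivws = [], [], []
        for _ in range(200):
            pleio = rng.normal(mu_pi, 0.005, 97)
            data, _ = simulate_summary(rng, k=97, theta=0.3, pleiotropy=pleio,
                                       alpha_dist="lognormal")
            e = mr_egger(data)
            intercepts.append(e.egger_intercept)
            slopes.append(e.estimate)
            ivws.append(mr_ivw(data).estimate)
        assert np.mean(intercepts) == pytest.approx(mu_pi, abs=0.005)
        # Egger slope stays near truth while IVW is biased upward
        assert abs(np.mean(slopes) - 0.3) < abs(np.mean(ivws) - 0.3)
        assert np.mean(ivws) > 0.35

    def test_null_intercept_p_uniform(self, rng):
        ps = []
        for _ in range(200):
            data, _ = simulate_summary(rng, k=50, theta=0.2)
            ps.append(mr_egger(data).p_intercept)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestWeightedMedian:
    def test_plain_median_under_equal_weights(self):
        est = _weighted_median_estimate(np.array([0.2, 0.5, 0.9]),
                                        np.ones(3))
        assert est == pytest.approx(0.5)

    def test_grid_oracle_on_random_instances(self, rng):
        # oracle: dense-grid minimiser of the weighted absolute deviation;
        # the interpolated crossing estimate must lie within one inter-ratio
        # gap of it (they coincide on the same median interval)
        for _ in range(20):
            ratios = rng.normal(0.4, 0.3, 9)
            weights = rng.uniform(0.1, 2.0, 9)
            est = _weighted_median_estimate(ratios, weights)
            grid = np.linspace(ratios.min(), ratios.max(), 4001)
            wad = np.abs(grid[:, None] - ratios[None, :]) @ weights
            oracle = grid[np.argmin(wad)]
            gap = np.max(np.diff(np.sort(ratios)))
            assert abs(est - oracle) <= gap + 1e-9

    def test_majority_valid_robustness(self, rng):
        # half the instruments carry large pleiotropy but only a minority of
        # the weight; the median tracks truth while IVW drifts
        k, theta = 30, 0.3
        alpha = np.r_[rng.uniform(0.08, 0.12, 15), rng.uniform(0.02, 0.04, 15)]
        sx = np.full(k, 0.004)
        sy = np.full(k, 0.01)
        pleio = np.r_[np.zeros(15), np.full(15, 0.05)]
        bx = rng.normal(alpha, sx)
        by = rng.normal(theta * alpha + pleio, sy)
        data = frame(bx, sx, by, sy)
        med = mr_weighted_median(data, n_boot=200, seed=1)
        ivw = mr_ivw(data)
        assert abs(med.estimate - theta) < 0.1
        assert abs(ivw.estimate - theta) > abs(med.estimate - theta)

    def test_too_few_finite_ratios_rejected(self):
        with pytest.raises(ValueError):
            mr_weighted_median(frame([0.0, 0.0, 0.1], [0.01] * 3,
                                     [0.1] * 3, [0.1] * 3))


class TestWeightedMode:
    def test_identical_ratios(self):
        bx = np.array([0.2, 0.4, 0.8])
        fit = mr_weighted_mode(frame(bx, [0.01] * 3, 0.5 * bx, [0.1] * 3),
                               n_boot=50, seed=0)
        assert fit.estimate == pytest.approx(0.5, abs=1e-9)

    def test_dominant_mode_wins(self):
        # 3 low-weight instruments at ratio 0, 6 high-weight at ratio 0.5
        bx = np.r_[np.full(3, 0.05), np.full(6, 0.3)]
        by = np.r_[np.zeros(3), 0.5 * np.full(6, 0.3)]
        fit = mr_weighted_mode(frame(bx, [0.01] * 9, by, [0.05] * 9),
                               n_boot=50, seed=0)
        assert fit.estimate == pytest.approx(0.5, abs=0.1)

    def test_density_flattens_as_bandwidth_grows(self, rng):
        ratios = rng.normal(0.4, 0.2, 25)
        weights = rng.uniform(0.5, 2.0, 25)
        contrasts = []
        for phi in (1.0, 5.0, 25.0):
            h = _mode_bandwidth(ratios, weights, phi)
            grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
            dens = (weights[None, :] * np.exp(
                -0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
            contrasts.append((dens.max() - dens.min()) / dens.max())
        assert contrasts[0] > contrasts[1] > contrasts[2]

    def test_zero_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            mr_weighted_mode(frame([0.1, 0.2, 0.3], [0.01] * 3,
                                   [0.05, 0.1, 0.15], [0.1] * 3),
                             bandwidth_factor=0.0)


class TestHeterogeneity:
    def test_zero_on_exact_line(self):
        bx = np.array([0.2, 0.5, 0.9])
        data = frame(bx, [0.01] * 3, 0.4 * bx, [0.1] * 3)
        fit = mr_ivw(data)
        Q, df, p = mr_heterogeneity(data, fit)
        assert Q == pytest.approx(0.0, abs=1e-18)
        assert df == 2

    def test_calibration_and_power(self, rng):
        from scipy import stats
        ps_null, ps_het = [], []
        for _ in range(200):
            data, _ = simulate_summary(rng, k=40, theta=0.3)
            ps_null.append(mr_ivw(data).p_Q)
            pleio = rng.normal(0.0, 0.03, 40)
            het, _ = simulate_summary(rng, k=40, theta=0.3, pleiotropy=pleio)
            ps_het.append(mr_ivw(het).p_Q)
        assert stats.kstest(ps_null, "uniform").pvalue > 0.01
        assert np.mean(np.asarray(ps_het) < 0.05) > 0.8


class TestInvariances:
    @given(st.floats(0.1, 10.0), st.integers(0, 10_000))
    def test_scale_equivariance_all_estimators(self, c, seed):
        rng = np.random.default_rng(seed)
        data, _ = simulate_summary(rng, k=12, theta=0.4)
        scaled = data.copy()
        scaled["bx"] *= c
        scaled["sx"] *= c
        for fn, kw in ((mr_ivw, {}), (mr_egger, {}),
                       (mr_weighted_median, {"n_boot": 20, "seed": 5}),
                       (mr_weighted_mode, {"n_boot": 20, "seed": 5})):
            a = fn(data, **kw)
            b = fn(scaled, **kw)
            assert b.estimate == pytest.approx(a.estimate / c, rel=1e-6,
                                               abs=1e-9)

    def test_harmonisation_invariance_under_label_flips(self, rng):
        k = 15
        bx = rng.normal(0.1, 0.03, k)
        by = rng.normal(0.04, 0.02, k)
        exp = make_table(bx, [0.01] * k, eafs=list(rng.uniform(0.2, 0.45, k)))
        out = make_table(by, [0.05] * k,
                         eafs=list(rng.uniform(0.2, 0.45, k)))
        base = TwoSampleMR(exp, out)

        def flipped(tab, sel):
            df = tab.df.copy()
            df.loc[sel, ["effect_allele", "other_allele"]] = \
                df.loc[sel, ["other_allele", "effect_allele"]].to_numpy()
            df.loc[sel, "beta"] = -df.loc[sel, "beta"]
            df.loc[sel, "eaf"] = 1 - df.loc[sel, "eaf"]
            return AssociationTable(df)

        sel = rng.random(k) < 0.5
        model = TwoSampleMR(flipped(exp, sel), flipped(out, sel))
        for method in ("ivw", "egger"):
            assert model.fit(method).estimate == pytest.approx(
                base.fit(method).estimate, abs=1e-12)

    def test_all_estimators_recover_truth_with_valid_instruments(self, rng):
        theta = np.log(1.59)
        sums = {"ivw": [], "egger": [], "weighted_median": [],
                "weighted_mode": []}
        for _ in range(200):
            data, _ = simulate_summary(rng, k=97, theta=theta)
            sums["ivw"].append(mr_ivw(data).estimate)
            sums["egger"].append(mr_egger(data).estimate)
            sums["weighted_median"].append(
                mr_weighted_median(data, n_boot=2, seed=0).estimate)
            sums["weighted_mode"].append(
                mr_weighted_mode(data, n_boot=2, seed=0).estimate)
        for method, vals in sums.items():
            bias = np.mean(vals) - theta
            assert abs(bias) < 0.05 * theta, (method, bias)


class TestLeaveOneStudyOut:
    def test_identical_cohorts_identical_fits(self, rng):
        bx = rng.uniform(0.05, 0.15, 10)
        exp = make_table(bx, [0.01] * 10)
        tabs = [make_table(0.5 * bx, [0.05] * 10, sample=f"c{i}")
                for i in range(3)]
        fits = mr_leave_one_study_out(tabs, exp)
        ests = [f.estimate for _, f in fits]
        assert ests[0] == pytest.approx(ests[1]) == pytest.approx(ests[2])

    def test_omitting_dominant_cohort_inflates_se(self, rng):
        bx = rng.uniform(0.05, 0.15, 10)
        exp = make_table(bx, [0.001] * 10)
        big = make_table(0.5 * bx, [0.01] * 10, sample="big")
        small = make_table(0.5 * bx, [0.2] * 10, sample="small")
        fits = dict(mr_leave_one_study_out([big, small], exp))
        assert fits["big"].se / fits["small"].se > 2

    def test_omitting_biased_cohort_moves_toward_truth(self, rng):
        theta = 0.3
        bx = rng.uniform(0.05, 0.15, 20)
        exp = make_table(bx, [0.001] * 20)
        clean = [make_table(rng.normal(theta * bx, 0.02), [0.02] * 20,
                            sample=f"clean{i}") for i in range(3)]
        biased = make_table(rng.normal(theta * bx + 0.05, 0.02), [0.02] * 20,
                            sample="biased")
        tabs = clean + [biased]
        from mrtri.meta import pool_per_snp
        from mrtri.summary import harmonised_frame
        full = mr_ivw(harmonised_frame(exp, pool_per_snp(tabs)))
        fits = dict(mr_leave_one_study_out(tabs, exp))
        assert abs(fits["biased"].estimate - theta) < abs(full.estimate - theta)

    def test_requires_two_cohorts(self):
        exp = make_table([0.1], [0.01])
        with pytest.raises(ValueError):
            mr_leave_one_study_out([exp], exp)


def test_summary_text_mentions_or_and_heterogeneity(rng):
    data, _ = simulate_summary(rng, k=20, theta=0.3)
    text = mr_ivw(data).summary()
    assert "OR per SD" in text and "Cochran" in text
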