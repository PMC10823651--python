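"""Two-sample Mendelian randomisation estimators and sensitivity suite.

All estimators consume a harmonised frame with one row per instrument and
columns ``bx, sx`` (SNP-exposure association, SD units of the exposure) and
``by, sy`` (SNP-outcome association, log-OR or SD units).  The causal
estimate is per SD of the exposure.

* IVW: weighted regression of by on bx through the origin with weights
  sy^-2; equivalent to the inverse-variance-weighted mean of per-SNP Wald
  ratios.  A multiplicative random-effects variant inflates the SE by
  max(1, sqrt(Q/df)).
* MR-Egger: the same regression with an unconstrained intercept after
  re-orienting every bx positive; the intercept estimates the average
  directional pleiotropy, the slope remains consistent under the InSIDE
  assumption.
* Weighted median: consistent when at least half the weight comes from
  valid instruments; bootstrap standard errors.
* Weighted mode: normal-kernel density over the per-SNP ratios, consistent
  when the largest homogeneous cluster of instruments is valid.

Heterogeneity between instruments is summarised by Cochran's Q; study-level
leave-one-out re-pools the cohort SNP-outcome tables (``meta`` module) and
re-runs IVW.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import pool_per_snp
from .summary import AssociationTable, harmonised_frame

Z95 = stats.norm.ppf(0.975)


@dataclass
class MRFit:
    """A causal estimate per SD of exposure with its diagnostics."""

    method: str  # ivw | egger | weighted_median | weighted_mode | wald
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_snps: int
    Q: float | None = None
    p_Q: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    p_intercept: float | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def p_value(self) -> float:
        return float(2 * stats.norm.sf(abs(self.estimate / self.se)))

    def summary(self) -> str:
        lines = [f"MR {self.method}: estimate {self.estimate:+.4f} "
                 f"(SE {self.se:.4f}; 95% CI {self.ci_low:+.4f}, "
                 f"{self.ci_high:+.4f}) over {self.n_snps} SNPs",
                 f"  OR per SD exposure: {self.odds_ratio:.3f}; "
                 f"p = {self.p_value:.3g}"]
        if self.Q is not None:
            lines.append(f"  Cochran's Q = {self.Q:.2f} (p = {self.p_Q:.3g})")
        if self.egger_intercept is not None:
            lines.append(f"  Egger intercept {self.egger_intercept:+.4f} "
                         f"(SE {self.egger_intercept_se:.4f}; "
                         f"p = {self.p_intercept:.3g})")
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {"method": self.method, "estimate": self.estimate, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_snps": self.n_snps, "Q": self.Q, "p_Q": self.p_Q,
                "egger_intercept": self.egger_intercept,
                "p_intercept": self.p_intercept}


def _columns(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        bx = data["bx"].to_numpy(float)
        sx = data["sx"].to_numpy(float)
        by = data["by"].to_numpy(float)
        sy = data["sy"].to_numpy(float)
    else:
        bx, sx, by, sy = (np.asarray(v, float) for v in data)
    if not (bx.size == sx.size == by.size == sy.size):
        raise ValueError("bx, sx, by, sy must have equal length")
    if bx.size == 0:
        raise ValueError("no instruments")
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise ValueError("standard errors must be > 0")
    return bx, sx, by, sy


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> tuple[float, float]:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if bx == 0:
        raise ZeroDivisionError("wald ratio undefined for bx = 0")
    return by / bx, sy / abs(bx)


def _fit(method, est, se, k, Q=None, dfQ=None, **extra) -> MRFit:
    p_Q = float(stats.chi2.sf(Q, dfQ)) if Q is not None and dfQ and dfQ > 0 else None
    return MRFit(method, float(est), float(se),
                 float(est - Z95 * se), float(est + Z95 * se), int(k),
                 Q=None if Q is None else float(Q), p_Q=p_Q, **extra)


def mr_ivw(data, effects_model: str = "fixed") -> MRFit:
    """Inverse-variance-weighted estimate.

    ``effects_model='multiplicative_random'`` scales the SE by
    max(1, sqrt(Q/df)) to absorb between-instrument heterogeneity.
    """
    bx, sx, by, sy = _columns(data)
    k = bx.size
    if k == 1:
        warnings.warn("single instrument: IVW degrades to the Wald ratio")
        est, se = wald_ratio(bx[0], sx[0], by[0], sy[0])
        return _fit("wald", est, se, 1)
    w = sy ** -2.0
    denom = float(w @ bx ** 2)
    est = float(w @ (bx * by)) / denom
    se = denom ** -0.5
    Q = float(w @ (by - est * bx) ** 2)
    df = k - 1
    if effects_model == "multiplicative_random":
        se *= max(1.0, np.sqrt(Q / df))
    elif effects_model != "fixed":
        raise ValueError(f"unknown effects_model {effects_model!r}")
    return _fit("ivw", est, se, k, Q, df)


def mr_egger(data) -> MRFit:
    """MR-Egger regression with directional-pleiotropy intercept.

    Instruments are re-oriented so every bx is positive (the intercept is
    only interpretable in a common orientation).  SEs carry the residual
    scale factor max(1, sqrt(Q_egger/(k-2))).
    """
    bx, sx, by, sy = _columns(data)
    k = bx.size
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise ValueError("MR-Egger undefined: no spread in exposure betas")
    w = sy ** -2.0
    X = np.column_stack([np.ones(k), bx])
    XtWX = (X * w[:, None]).T @ X
    coef = np.linalg.solve(XtWX, (X * w[:, None]).T @ by)
    resid = by - X @ coef
    Q = float(w @ resid ** 2)
    df = k - 2
    scale = max(1.0, np.sqrt(Q / df))
    cov = np.linalg.inv(XtWX) * scale ** 2
    inter, slope = coef
    se_inter, se_slope = np.sqrt(np.diag(cov))
    p_inter = float(2 * stats.norm.sf(abs(inter / se_inter)))
    return _fit("egger", slope, se_slope, k, Q, df,
                egger_intercept=float(inter),
                egger_intercept_se=float(se_inter),
                p_intercept=p_inter)


def _weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weight per SNP
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    below = np.max(np.where(cum < 0.5)[0])
    # linear interpolation between the bracketing ratios
    f = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r[below] + f * (r[below + 1] - r[below]))


def _finite_ratio_arrays(bx, sx, by, sy, min_k: int):
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = by / bx
    keep = np.isfinite(ratios)
    if keep.sum() < min_k:
        raise ValueError(f"fewer than {min_k} instruments with finite ratios")
    return bx[keep], sx[keep], by[keep], sy[keep], ratios[keep]


def mr_weighted_median(data, n_boot: int = 1000, seed: int = 0) -> MRFit:
    """Weighted-median estimate with parametric-bootstrap SE.

    Weights are bx^2/sy^2 (the inverse variance of each Wald ratio to first
    order); the estimate is the ratio at which the cumulative standardized
    weight crosses one half, linearly interpolated.
    """
    bx, sx, by, sy = _columns(data)
    bx, sx, by, sy, ratios = _finite_ratio_arrays(bx, sx, by, sy, 3)
    weights = bx ** 2 / sy ** 2
    est = _weighted_median_estimate(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0
        boots[i] = _weighted_median_estimate(by_b[ok] / bx_b[ok],
                                             bx_b[ok] ** 2 / sy[ok] ** 2)
    se = float(boots.std(ddof=1))
    return _fit("weighted_median", est, se, bx.size)


def _mode_bandwidth(ratios: np.ndarray, weights: np.ndarray,
                    bandwidth_factor: float) -> float:
    w = weights / weights.sum()
    mean = w @ ratios
    sd = np.sqrt(w @ (ratios - mean) ** 2)
    order = np.argsort(ratios)
    cum = np.cumsum(w[order])
    i25 = min(int(np.searchsorted(cum, 0.25)), ratios.size - 1)
    i75 = min(int(np.searchsorted(cum, 0.75)), ratios.size - 1)
    iqr = ratios[order][i75] - ratios[order][i25]
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = bandwidth_factor * 0.9 * spread * ratios.size ** (-1 / 5)
    if h <= 0:
        raise ValueError("zero kernel bandwidth: ratios are degenerate")
    return float(h)


def _weighted_mode_estimate(ratios: np.ndarray, weights: np.ndarray,
                            bandwidth_factor: float) -> float:
    if np.ptp(ratios) == 0:
        return float(ratios[0])
    h = _mode_bandwidth(ratios, weights, bandwidth_factor)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = (weights[None, :]
            * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mr_weighted_mode(data, bandwidth_factor: float = 1.0,
                     n_boot: int = 1000, seed: int = 0) -> MRFit:
    """Weighted-mode estimate (kernel-density argmax over Wald ratios).

    Bandwidth is ``bandwidth_factor * 0.9 * min(sd, IQR/1.349) * k^(-1/5)``
    on the ratio scale with inverse-variance weights; SE by parametric
    bootstrap.
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be > 0")
    bx, sx, by, sy = _columns(data)
    bx, sx, by, sy, ratios = _finite_ratio_arrays(bx, sx, by, sy, 3)
    weights = bx ** 2 / sy ** 2
    est = _weighted_mode_estimate(ratios, weights, bandwidth_factor)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0
        boots[i] = _weighted_mode_estimate(by_b[ok] / bx_b[ok],
                                           bx_b[ok] ** 2 / sy[ok] ** 2,
                                           bandwidth_factor)
    se = float(boots.std(ddof=1))
    return _fit("weighted_mode", est, se, bx.size)


def mr_heterogeneity(data, fit: MRFit) -> tuple[float, int, float]:
    """Cochran's Q about a fitted MR model (df = k-1, or k-2 for Egger)."""
    bx, sx, by, sy = _columns(data)
    k = bx.size
    if k < 2:
        raise ValueError("heterogeneity needs at least 2 instruments")
    pred = fit.estimate * bx
    df = k - 1
    if fit.method == "egger":
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        pred = flip * (fit.egger_intercept + fit.estimate * (bx * flip))
        df = k - 2
    Q = float(sy ** -2.0 @ (by - pred) ** 2)
    return Q, df, float(stats.chi2.sf(Q, df))


def mr_leave_one_study_out(cohort_tables: list[AssociationTable],
                           exposure: AssociationTable,
                           method: str = "fixed",
                           effects_model: str = "fixed",
                           labels=None) -> list[tuple[str, MRFit]]:
    """Re-pool SNP-outcome tables without each cohort and re-run IVW."""
    if len(cohort_tables) < 2:
        raise ValueError("leave-one-study-out requires at least 2 cohorts")
    if labels is None:
        labels = [t.sample or f"cohort_{i}" for i, t in enumerate(cohort_tables)]
    fits = []
    for i, label in enumerate(labels):
        rest = [t for j, t in enumerate(cohort_tables) if j != i]
        pooled = pool_per_snp(rest, method=method)
        frame = harmonised_frame(exposure, pooled)
        fits.append((label, mr_ivw(frame, effects_model=effects_model)))
    return fits


class TwoSampleMR:
    """Model object holding harmonised two-sample summary data.

    Construct from an exposure and an outcome :class:`AssociationTable`;
    harmonisation to the exposure's effect alleles happens on construction.
    ``fit(method)`` returns an :class:`MRFit`; ``fit_all()`` runs the main
    IVW analysis plus the sensitivity estimators.
    """

    METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")

    def __init__(self, exposure: AssociationTable, outcome: AssociationTable,
                 **harmonise_kwargs):
        self.exposure = exposure
        self.outcome = outcome
        self.data = harmonised_frame(exposure, outcome, **harmonise_kwargs)

    @property
    def n_snps(self) -> int:
        return len(self.data)

    def fit(self, method: str = "ivw", **kwargs) -> MRFit:
        if method == "ivw":
            return mr_ivw(self.data, **kwargs)
        if method == "egger":
            return mr_egger(self.data, **kwargs)
        if method == "weighted_median":
            return mr_weighted_median(self.data, **kwargs)
        if method == "weighted_mode":
            return mr_weighted_mode(self.data, **kwargs)
        raise ValueError(f"unknown MR method {method!r}")

    def fit_all(self, n_boot: int = 1000, seed: int = 0,
                effects_model: str = "fixed") -> dict[str, MRFit]:
        return {
            "ivw": self.fit("ivw", effects_model=effects_model),
            "egger": self.fit("egger"),
            "weighted_median": self.fit("weighted_median", n_boot=n_boot,
                                        seed=seed),
            "weighted_mode": self.fit("weighted_mode", n_boot=n_boot,
                                      seed=seed),
        }

    def heterogeneity(self, fit: MRFit | None = None):
        if fit is None:
            fit = self.fit("ivw")
        return mr_heterogeneity(self.data, fit)


def mr_fits_to_tsv(fits: dict[str, MRFit] | list[MRFit], outcome: str, path) -> None:
    items = fits.values() if isinstance(fits, dict) else fits
    rows = [{"outcome": outcome, **f.to_row()} for f in items]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")
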