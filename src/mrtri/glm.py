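"""Regression engines for the individual-level analysis arms.

Logistic models are fitted by iteratively reweighted least squares (Newton
scoring on the Bernoulli log-likelihood) to a score tolerance of 1e-8;
linear models by (weighted) least squares.  Frequency weights allow exact
fitting on aggregated data, which makes per-SNP genotype scans over large
cohorts cheap: a 0/1/2-coded genotype regression collapses to at most six
covariate-outcome cells.

Perfect separation and rank deficiency are raised as explicit errors rather
than silently penalised or dropped — downstream meta-analysis weights would
otherwise be distorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


class SeparationError(RuntimeError):
    """Logistic likelihood is unbounded (perfectly separated data)."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the offending column."""


@dataclass
class GLMResult:
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    converged: bool
    n_iter: int
    family: str
    nobs: float
    names: list[str] = field(default_factory=list)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy import stats
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])


def _check_design(X: np.ndarray, names: list[str]) -> None:
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} observations for p={p} parameters")
    # incremental rank check to name the first dependent column
    if np.linalg.matrix_rank(X) < p:
        for j in range(1, p + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise RankDeficiencyError(
                    f"design matrix is rank deficient at column {names[j - 1]!r}")
        raise RankDeficiencyError("design matrix is rank deficient")


def fit_glm(y, X, family: str = "logistic", freq_weights=None,
            tol: float = 1e-8, max_iter: int = 50,
            names: list[str] | None = None) -> GLMResult:
    """Fit a logistic or linear model of ``y`` on the design matrix ``X``.

    ``X`` must already contain an intercept column if one is wanted.
    ``freq_weights`` replicate rows (grouped data); standard errors come from
    the inverse Fisher information (logistic) or the residual variance
    (linear).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    w = np.ones(n) if freq_weights is None else np.asarray(freq_weights, float)
    nobs = float(w.sum())
    if nobs <= p:
        raise ValueError(f"effective n={nobs} for p={p} parameters")
    _check_design(X, names)

    if family == "linear":
        Xw = X * np.sqrt(w)[:, None]
        yw = y * np.sqrt(w)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        resid = y - X @ beta
        sigma2 = float(w @ resid ** 2) / (nobs - p)
        cov = sigma2 * np.linalg.inv(XtX)
        bse = np.sqrt(np.diag(cov))
        return GLMResult(beta, bse, cov, True, 1, "linear", nobs, names)

    if family != "logistic":
        raise ValueError(f"unknown family {family!r}")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("logistic family requires 0/1 outcomes")

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (w * (y - mu))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        wls = w * mu * (1.0 - mu)
        if np.max(wls) < 1e-12:
            raise SeparationError("all fitted probabilities degenerate at 0 or 1")
        XtWX = (X * wls[:, None]).T @ X
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as err:
            raise SeparationError(f"information matrix singular: {err}") from err
        # dampen absurd steps; divergence beyond this signals separation
        step = np.max(np.abs(delta))
        if step > 50:
            delta *= 50 / step
        beta = beta + delta
        if np.max(np.abs(beta)) > 1e3:
            raise SeparationError(
                "coefficients diverging; data are likely perfectly separated")
    if not converged:
        # distinguish slow convergence from separation
        eta = X @ beta
        mu = expit(eta)
        if np.max(np.abs(beta)) > 30 or np.min(mu * (1 - mu)) < 1e-10:
            raise SeparationError(
                "logistic fit failed to converge; data are likely separated")
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")

    if np.max(np.abs(beta)) > 30:
        # gradient can vanish at a saturated fit; enormous log-odds mean the
        # MLE does not exist in the interior
        raise SeparationError(
            "coefficients exceed 30 on the log-odds scale; "
            "data are likely perfectly separated")
    mu = expit(X @ beta)
    wls = w * mu * (1.0 - mu)
    XtWX = (X * wls[:, None]).T @ X
    cov = np.linalg.inv(XtWX)
    bse = np.sqrt(np.diag(cov))
    return GLMResult(beta, bse, cov, True, it, "logistic", nobs, names)


def fit_glm_grouped_binary(y01_counts: np.ndarray, X: np.ndarray, **kwargs) -> GLMResult:
    """Fit a logistic model on aggregated cells.

    ``y01_counts`` has two columns (count of controls, count of cases) per
    design row of ``X``; cells with zero total are allowed and ignored.
    """
    counts = np.asarray(y01_counts, float)
    keep = counts.sum(axis=1) > 0
    counts, X = counts[keep], np.asarray(X, float)[keep]
    k = X.shape[0]
    Xrep = np.vstack([X, X])
    y = np.concatenate([np.zeros(k), np.ones(k)])
    w = np.concatenate([counts[:, 0], counts[:, 1]])
    nz = w > 0
    return fit_glm(y[nz], Xrep[nz], family="logistic", freq_weights=w[nz], **kwargs)
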