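"""Propensity scores, overlap weights, and the ATO estimator.

The estimand is the average treatment effect in the overlap population
(ATO).  A logistic propensity model e(x) = P(Z=1 | x) is fit on age, sex,
BMI, job position and the baseline value of the outcome under analysis (one
propensity model per outcome); overlap weights are w = 1 - e for the
intervention arm and w = e for the control arm, with no trimming or
truncation.  The effect estimate is the Hajek contrast of overlap-weighted
mean change scores, and its variance comes from the M-estimation sandwich
over the stacked estimating equations (logistic scores + weighted-mean
equations), so propensity-estimation uncertainty propagates.  A
weights-held-fixed variance is available for sensitivity.

With a logistic propensity model, overlap weights balance every covariate in
the model *exactly* (their weighted means agree between arms to solver
precision) — asserted as a diagnostic on every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class PSModel:
    """A fitted logistic propensity model."""

    coefficients: np.ndarray
    ps: np.ndarray          # fitted propensity per subject, in (0, 1)
    X: np.ndarray           # design with leading intercept column
    z: np.ndarray           # group indicator (1 = intervention)
    converged: bool
    names: list


@dataclass
class OverlapWeights:
    weights: np.ndarray
    z: np.ndarray
    ps: np.ndarray


@dataclass
class WeightedEstimate:
    """ATO effect estimate with within-arm weighted means and sandwich inference."""

    diff: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    mean_treated: float
    se_treated: float
    mean_control: float
    se_control: float
    n: int


def fit_ps_logistic(X: np.ndarray | pd.DataFrame, z: np.ndarray,
                    names: list | None = None) -> PSModel:
    """Maximum-likelihood logistic propensity fit (IRLS via statsmodels GLM).

    ``X`` holds the covariate columns (no intercept; one is added).  Raises on
    non-convergence or on fitted propensities numerically at 0 or 1, which
    indicates separation.
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.isnan(X).any() or np.isnan(z).any():
        raise ValueError("propensity model requires complete covariates")
    if z.min() == z.max():
        raise ValueError("both groups must be represented")
    design = sm.add_constant(X, has_constant="add")
    model = sm.GLM(z, design, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    ps = np.asarray(res.fittedvalues, dtype=float)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("propensity fit did not converge (non-finite coefficients)")
    if np.any(ps <= 1e-10) or np.any(ps >= 1.0 - 1e-10):
        j = int(np.argmax(np.abs(res.params[1:]))) if len(res.params) > 1 else 0
        label = (names[j] if names else f"x{j}")
        raise RuntimeError(
            f"fitted propensities at the boundary; separation suspected "
            f"(largest coefficient: {label})")
    return PSModel(coefficients=np.asarray(res.params), ps=ps, X=design, z=z,
                   converged=res.converged, names=names or
                   [f"x{i}" for i in range(X.shape[1])])


def compute_overlap_weights(model: PSModel) -> OverlapWeights:
    """Overlap weights: 1 - e(x) for the intervention arm, e(x) for controls."""
    ps = model.ps
    if np.any(ps <= 0.0) or np.any(ps >= 1.0):
        raise ValueError("propensities must lie strictly in (0, 1)")
    z = model.z
    w = z * (1.0 - ps) + (1.0 - z) * ps
    return OverlapWeights(weights=w, z=z, ps=ps)


def estimate_ato(y: np.ndarray, ow: OverlapWeights) -> tuple[float, float, float]:
    """Hajek point estimates: (difference, treated mean, control mean)."""
    y = np.asarray(y, dtype=float)
    w, z = ow.weights, ow.z
    wt = w * z
    wc = w * (1.0 - z)
    if wt.sum() <= 0 or wc.sum() <= 0:
        raise ValueError("an arm has zero total weight")
    mu1 = float(np.sum(wt * y) / wt.sum())
    mu0 = float(np.sum(wc * y) / wc.sum())
    return mu1 - mu0, mu1, mu0


def _sandwich_cov(model: PSModel, y: np.ndarray, mu1: float, mu0: float,
                  method: str = "stacked") -> np.ndarray:
    """Covariance of (mu1, mu0) from the stacked estimating equations.

    Stack: logistic score equations for the propensity coefficients gamma,
    then the two weighted-mean equations
        sum_i Z_i (1 - e_i)(Y_i - mu1) = 0,
        sum_i (1 - Z_i) e_i (Y_i - mu0) = 0.
    A is the (negated) mean Jacobian, B the outer-product mean;
    cov(theta-hat) = A^-1 B A^-T / n.  ``method='fixed'`` drops the gamma
    rows (weights treated as known).
    """
    X, z, e = model.X, model.z, model.ps
    n, p = X.shape
    w1 = z * (1.0 - e)
    w0 = (1.0 - z) * e
    if method == "fixed":
        psi = np.column_stack([w1 * (y - mu1), w0 * (y - mu0)])
        A = np.diag([w1.mean(), w0.mean()])
    elif method == "stacked":
        psi_g = (z - e)[:, None] * X
        psi = np.column_stack([psi_g, w1 * (y - mu1), w0 * (y - mu0)])
        A = np.zeros((p + 2, p + 2))
        v = e * (1.0 - e)
        A[:p, :p] = (X * v[:, None]).T @ X / n
        A[p, :p] = (z * v * (y - mu1)) @ X / n
        A[p + 1, :p] = -((1.0 - z) * v * (y - mu0)) @ X / n
        A[p, p] = w1.mean()
        A[p + 1, p + 1] = w0.mean()
    else:
        raise ValueError("method must be 'stacked' or 'fixed'")
    B = psi.T @ psi / n
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise RuntimeError(f"singular bread matrix (condition number {cond:.3g})")
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv.T / n
    return cov[-2:, -2:]


def ato_inference(model: PSModel, y: np.ndarray,
                  method: str = "stacked") -> WeightedEstimate:
    """ATO estimate with sandwich SE, normal 95% CI and two-sided P."""
    ow = compute_overlap_weights(model)
    diff, mu1, mu0 = estimate_ato(y, ow)
    cov = _sandwich_cov(model, np.asarray(y, dtype=float), mu1, mu0, method)
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    se = float(np.sqrt(max(var_diff, 0.0)))
    se1 = float(np.sqrt(max(cov[0, 0], 0.0)))
    se0 = float(np.sqrt(max(cov[1, 1], 0.0)))
    zcrit = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(diff) / se) if se > 0 else (0.0 if diff else 1.0)
    return WeightedEstimate(diff=diff, se=se, ci_low=diff - zcrit * se,
                            ci_high=diff + zcrit * se, p=float(p),
                            mean_treated=mu1, se_treated=se1,
                            mean_control=mu0, se_control=se0, n=y.size)


def balance_diagnostics(covariates: pd.DataFrame, ow: OverlapWeights) -> pd.DataFrame:
    """Standardized mean differences per covariate, unweighted and weighted.

    The weighted SMD of every covariate in the propensity model should be
    zero to numerical precision (exact-balance property of overlap weights
    under a logistic propensity model).
    """
    z = ow.z.astype(bool)
    w = ow.weights
    rows = []
    for col in covariates.columns:
        x = covariates[col].to_numpy(dtype=float)
        m1, m0 = x[z].mean(), x[~z].mean()
        s = np.sqrt((x[z].var(ddof=1) + x[~z].var(ddof=1)) / 2.0)
        wm1 = np.sum(w[z] * x[z]) / np.sum(w[z])
        wm0 = np.sum(w[~z] * x[~z]) / np.sum(w[~z])
        rows.append({
            "covariate": col,
            "smd_unweighted": (m1 - m0) / s if s > 0 else np.nan,
            "smd_weighted": (wm1 - wm0) / s if s > 0 else np.nan,
            "weighted_mean_diff": wm1 - wm0,
        })
    return pd.DataFrame(rows)


def assert_exact_balance(model: PSModel, tol: float = 1e-6) -> float:
    """Largest weighted-mean covariate imbalance; raises above ``tol``."""
    ow = compute_overlap_weights(model)
    X = model.X[:, 1:]  # drop intercept
    z = model.z.astype(bool)
    w = ow.weights
    wm1 = (w[z, None] * X[z]).sum(axis=0) / w[z].sum()
    wm0 = (w[~z, None] * X[~z]).sum(axis=0) / w[~z].sum()
    worst = float(np.max(np.abs(wm1 - wm0))) if X.shape[1] else 0.0
    if worst > tol:
        raise RuntimeError(f"overlap weights failed exact balance: {worst:.3g}")
    return worst
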