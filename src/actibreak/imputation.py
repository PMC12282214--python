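"""Multiple imputation by chained equations with predictive mean matching,
and Rubin's-rule pooling.

The imputation model is the one the study names: chained equations sweep the
incomplete variables in turn, each imputed by predictive mean matching (PMM).
The PMM variant is type-1 matching: donors are ranked by their least-squares
predictions while the missing cases use predictions under a Bayesian
parameter draw, and each missing cell receives the *observed* value of one of
the ``k`` nearest-predicted donors chosen uniformly — imputed values are
always observed values, never model predictions.  Twenty imputed datasets are
the study default; each downstream estimate is combined across datasets by
Rubin's rules with the Barnard-Rubin degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ImputationSpec


@dataclass
class PooledEstimate:
    """Rubin-combined estimate over m imputed datasets.

    total variance T = W + (1 + 1/m) B, where W is the mean within-imputation
    variance and B the between-imputation variance of the estimates.
    """

    estimate: float
    se: float
    W: float
    B: float
    T: float
    df: float
    ci_low: float
    ci_high: float
    p: float
    m: int


def pool_rubin(estimates, variances, alpha: float = 0.05) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 (B is undefined at m=1)")
    if np.any(u < 0):
        raise ValueError("variances must be non-negative")
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        r = (1.0 + 1.0 / m) * B / W if W > 0 else np.inf
        df = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) else m - 1.0
    else:
        df = np.inf
    se = float(np.sqrt(T))
    if np.isfinite(df):
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        p = 2.0 * stats.t.sf(abs(qbar) / se, df) if se > 0 else (0.0 if qbar else 1.0)
    else:
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
        p = 2.0 * stats.norm.sf(abs(qbar) / se) if se > 0 else (0.0 if qbar else 1.0)
    return PooledEstimate(estimate=qbar, se=se, W=W, B=B, T=T, df=float(df),
                          ci_low=qbar - crit * se, ci_high=qbar + crit * se,
                          p=float(p), m=m)


def _posterior_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Least-squares fit plus a draw from the approximate parameter posterior.

    Returns (beta_hat, beta_star): beta_star = beta_hat + chol(sigma*^2
    (X'X)^-1) z with sigma*^2 from the scaled inverse chi-square.
    """
    n, p = X.shape
    XtX = X.T @ X
    # ridge jitter guards against exactly collinear sweeps
    XtX_reg = XtX + 1e-8 * np.eye(p) * max(np.trace(XtX) / p, 1.0)
    beta_hat = np.linalg.solve(XtX_reg, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2_star = sigma2_hat * dof / rng.chisquare(dof)
    cov = sigma2_star * np.linalg.inv(XtX_reg)
    cov = (cov + cov.T) / 2.0
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
        beta_star = beta_hat + L @ rng.standard_normal(p)
    except np.linalg.LinAlgError:
        beta_star = beta_hat
    return beta_hat, beta_star


def _pmm_once(y: np.ndarray, X: np.ndarray, miss: np.ndarray, k: int,
              rng: np.random.Generator) -> np.ndarray:
    """One PMM update of a single variable; returns imputed values."""
    obs = ~miss
    beta_hat, beta_star = _posterior_draw(X[obs], y[obs], rng)
    pred_obs = X[obs] @ beta_hat
    pred_mis = X[miss] @ beta_star
    y_obs = y[obs]
    k_eff = min(k, y_obs.size)
    # distance matrix |pred_obs - pred_mis| is small (n_mis x n_obs)
    d = np.abs(pred_obs[None, :] - pred_mis[:, None])
    nearest = np.argpartition(d, k_eff - 1, axis=1)[:, :k_eff]
    pick = rng.integers(0, k_eff, size=nearest.shape[0])
    return y_obs[nearest[np.arange(nearest.shape[0]), pick]]


def impute_pmm(data: pd.DataFrame, spec: ImputationSpec,
               columns: list[str] | None = None,
               predictors: list[str] | None = None,
               predictor_map: dict | None = None) -> list[pd.DataFrame]:
    """Generate ``spec.m`` completed datasets by chained-equation PMM.

    ``columns`` are the variables to impute (default: every column with at
    least one missing value); ``predictors`` are additional fully observed
    columns to condition on (default: all remaining numeric columns).
    ``predictor_map`` overrides the predictor set per imputed variable —
    used to keep linearly dependent variables (e.g. compositional behavior
    minutes that sum to a constant) out of each other's equations.
    Categorical variables coded numerically are imputed by PMM on their
    coding, so imputations stay on the observed support.
    """
    work_cols = columns or [c for c in data.columns if data[c].isna().any()]
    for c in work_cols:
        if data[c].notna().sum() == 0:
            raise ValueError(f"cannot impute {c!r}: no observed cases")
    numeric = [c for c in data.columns
               if np.issubdtype(np.asarray(data[c]).dtype, np.number)]
    pred_pool = predictors if predictors is not None else numeric
    pred_pool = [c for c in pred_pool if c in numeric]

    base = data[numeric].to_numpy(dtype=float)
    col_ix = {c: numeric.index(c) for c in numeric}
    miss_mask = np.isnan(base)
    targets = [c for c in work_cols if miss_mask[:, col_ix[c]].any()]
    if not targets:
        return [data.copy() for _ in range(spec.m)]

    ss = np.random.SeedSequence(spec.seed)
    out = []
    for child in ss.spawn(spec.m):
        rng = np.random.default_rng(child)
        filled = base.copy()
        for c in targets:
            j = col_ix[c]
            mis = miss_mask[:, j]
            obs_vals = base[~mis, j]
            filled[mis, j] = rng.choice(obs_vals, size=int(mis.sum()))
        for _ in range(spec.n_iterations):
            for c in targets:
                j = col_ix[c]
                mis = miss_mask[:, j]
                pool_c = (predictor_map or {}).get(c, pred_pool)
                pred_cols = [col_ix[p] for p in pool_c if p != c and p in col_ix]
                X = filled[:, pred_cols]
                keep = np.std(X[~mis], axis=0) > 1e-12
                if not keep.all():
                    warnings.warn(f"dropping constant predictors for {c!r}",
                                  stacklevel=2)
                    X = X[:, keep]
                X = np.column_stack([np.ones(X.shape[0]), X])
                filled[mis, j] = _pmm_once(filled[:, j], X, mis,
                                           spec.k_donors, rng)
        df = data.copy()
        for c in numeric:
            df[c] = filled[:, col_ix[c]]
        out.append(df)
    return out
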