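"""Propensity scores, overlap weights, Hajek ATO, sandwich variance."""

import numpy as np
import pandas as pd
import pytest

from actibreak.causal import (OverlapWeights, assert_exact_balance,
                              ato_inference, balance_diagnostics,
                              compute_overlap_weights, estimate_ato,
                              fit_ps_logistic)
from actibreak.pipeline import PS_COVARIATES, build_analysis_table
from actibreak.synthetic import simulate_cohort
from tests.conftest import no_missingness
from actibreak.config import CohortConfig


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# propensity fitting

def test_intercept_only_ps_equals_prevalence(rng):
    z = (rng.random(200) < 0.3).astype(float)
    model = fit_ps_logistic(np.empty((200, 0)), z)
    np.testing.assert_allclose(model.ps, z.mean(), atol=1e-8)


def test_fitted_ps_mean_equals_prevalence(rng):
    """Score-equation identity of the ML logistic fit."""
    X = rng.normal(0, 1, (400, 3))
    z = (rng.random(400) < _sigmoid(X @ [0.5, -0.3, 0.2])).astype(float)
    model = fit_ps_logistic(X, z)
    assert model.ps.mean() == pytest.approx(z.mean(), abs=1e-8)
    assert np.all((model.ps > 0) & (model.ps < 1))


def test_ps_coefficients_recovered_from_known_model(rng):
    n = 5000
    X = rng.normal(0, 1, (n, 2))
    truth = np.array([-0.4, 0.8, -0.6])
    z = (rng.random(n) < _sigmoid(truth[0] + X @ truth[1:])).astype(float)
    model = fit_ps_logistic(X, z)
    import statsmodels.api as sm
    se = sm.Logit(z, sm.add_constant(X)).fit(disp=0).bse
    assert np.all(np.abs(model.coefficients - truth) < 3 * se)


def test_perfect_separation_raises(rng):
    x = np.concatenate([np.zeros(20), np.ones(20)])[:, None]
    z = np.concatenate([np.zeros(20), np.ones(20)])
    with pytest.raises(RuntimeError, match="separation"):
        fit_ps_logistic(x, z)


def test_missing_covariates_rejected():
    X = np.array([[1.0], [np.nan]])
    with pytest.raises(ValueError):
        fit_ps_logistic(X, np.array([0.0, 1.0]))


# ---------------------------------------------------------------------------
# overlap weights

def _weights_from(ps, z):
    model = type("M", (), {})()
    ow = OverlapWeights(weights=z * (1 - ps) + (1 - z) * ps, z=z, ps=ps)
    return ow


@pytest.mark.parametrize("z, e, w", [
    (1.0, 0.5, 0.5),   # symmetric point
    (0.0, 0.9, 0.9),   # control weighted by the propensity itself
    (1.0, 0.9, 0.1),   # treated at extreme propensity is down-weighted
])
def test_overlap_weight_values(rng, z, e, w):
    zv = np.array([z, 1.0 - z])
    ev = np.array([e, 0.5])
    model = type("M", (), {"ps": ev, "z": zv})()
    ow = compute_overlap_weights(model)
    assert ow.weights[0] == pytest.approx(w)


def test_treated_weight_vanishes_as_ps_tends_to_one():
    z = np.array([1.0, 0.0])
    for e in (0.9, 0.99, 0.999):
        model = type("M", (), {"ps": np.array([e, 0.5]), "z": z})()
        assert compute_overlap_weights(model).weights[0] == pytest.approx(1 - e)


def test_boundary_ps_rejected():
    model = type("M", (), {"ps": np.array([0.0, 0.5]),
                           "z": np.array([1.0, 0.0])})()
    with pytest.raises(ValueError):
        compute_overlap_weights(model)


# ---------------------------------------------------------------------------
# ATO point estimate

def test_ato_hand_arithmetic_oracle():
    """Treated Y=(10,20) w=(0.25,0.75); control Y=(0,10) w=(0.5,0.5)."""
    y = np.array([10.0, 20.0, 0.0, 10.0])
    z = np.array([1.0, 1.0, 0.0, 0.0])
    ow = OverlapWeights(weights=np.array([0.25, 0.75, 0.5, 0.5]), z=z,
                        ps=np.full(4, 0.5))
    diff, mu1, mu0 = estimate_ato(y, ow)
    assert mu1 == pytest.approx(17.5)
    assert mu0 == pytest.approx(5.0)
    assert diff == pytest.approx(12.5)


def test_equal_weights_reduce_to_difference_of_means(rng):
    y = rng.normal(0, 1, 100)
    z = (rng.random(100) < 0.5).astype(float)
    ow = OverlapWeights(weights=np.full(100, 0.37), z=z, ps=np.full(100, 0.5))
    diff, _, _ = estimate_ato(y, ow)
    assert diff == pytest.approx(y[z == 1].mean() - y[z == 0].mean())


def test_constant_outcome_gives_zero_effect(rng):
    z = (rng.random(50) < 0.4).astype(float)
    ow = OverlapWeights(weights=rng.random(50) * 0.9 + 0.05, z=z,
                        ps=np.full(50, 0.5))
    diff, _, _ = estimate_ato(np.full(50, 3.3), ow)
    assert diff == pytest.approx(0.0)


def test_empty_arm_weight_is_error():
    y = np.array([1.0, 2.0])
    ow = OverlapWeights(weights=np.array([0.5, 0.5]), z=np.array([1.0, 1.0]),
                        ps=np.array([0.5, 0.5]))
    with pytest.raises(ValueError):
        estimate_ato(y, ow)


# ---------------------------------------------------------------------------
# sandwich variance

def test_intercept_only_sandwich_equals_two_sample_robust_se(rng):
    n = 300
    z = (rng.random(n) < 0.4).astype(float)
    y = rng.normal(1.0, 2.0, n) + z
    model = fit_ps_logistic(np.empty((n, 0)), z)
    est = ato_inference(model, y)
    n1, n0 = z.sum(), n - z.sum()
    closed = np.sqrt(y[z == 1].var() / n1 + y[z == 0].var() / n0)
    assert est.se == pytest.approx(closed, rel=1e-6)
    assert est.diff == pytest.approx(y[z == 1].mean() - y[z == 0].mean())


def test_sandwich_within_ten_percent_of_bootstrap(rng):
    """500-resample nonparametric bootstrap oracle at n=200."""
    n = 200
    X = rng.normal(0, 1, (n, 2))
    z = (rng.random(n) < _sigmoid(0.3 * X[:, 0] - 0.4 * X[:, 1])).astype(float)
    y = 0.5 * X[:, 0] + rng.normal(0, 1, n) + 1.2 * z
    model = fit_ps_logistic(X, z)
    est = ato_inference(model, y)
    boot = []
    for _ in range(500):
        idx = rng.integers(0, n, n)
        if z[idx].min() == z[idx].max():
            continue
        m = fit_ps_logistic(X[idx], z[idx])
        ow = compute_overlap_weights(m)
        boot.append(estimate_ato(y[idx], ow)[0])
    ratio = est.se / np.std(boot, ddof=1)
    assert 0.9 < ratio < 1.1


def test_doubling_outcome_scale_doubles_se(rng):
    n = 150
    X = rng.normal(0, 1, (n, 1))
    z = (rng.random(n) < 0.5).astype(float)
    y = rng.normal(0, 1, n)
    model = fit_ps_logistic(X, z)
    a = ato_inference(model, y)
    b = ato_inference(model, 2.0 * y)
    assert b.se == pytest.approx(2.0 * a.se, rel=1e-9)
    assert b.diff == pytest.approx(2.0 * a.diff, rel=1e-9)


def test_location_shift_leaves_effect_unchanged(rng):
    n = 150
    X = rng.normal(0, 1, (n, 1))
    z = (rng.random(n) < 0.5).astype(float)
    y = rng.normal(0, 1, n)
    model = fit_ps_logistic(X, z)
    a = ato_inference(model, y)
    b = ato_inference(model, y + 7.5)
    assert b.diff == pytest.approx(a.diff, abs=1e-9)
    assert b.se == pytest.approx(a.se, rel=1e-9)
    assert b.mean_treated == pytest.approx(a.mean_treated + 7.5)


def test_fixed_weight_variant_ignores_ps_estimation(rng):
    n = 250
    X = rng.normal(0, 1, (n, 2))
    z = (rng.random(n) < _sigmoid(0.5 * X[:, 0])).astype(float)
    y = rng.normal(0, 1, n)
    model = fit_ps_logistic(X, z)
    stacked = ato_inference(model, y, method="stacked")
    fixed = ato_inference(model, y, method="fixed")
    assert stacked.diff == pytest.approx(fixed.diff)
    assert stacked.se != pytest.approx(fixed.se, rel=1e-6)


# ---------------------------------------------------------------------------
# balance

def _cohort_table(seed):
    cfg = CohortConfig(seed=seed, wear_days_override=5,
                       missingness=no_missingness())
    cohort = simulate_cohort(cfg, mode="tabular", seed=seed)
    return build_analysis_table(cohort, ("sb",))


def test_overlap_weights_balance_model_covariates_exactly():
    """Weighted means of every propensity-model covariate agree across arms
    to numerical precision (exact-balance property of overlap weights)."""
    t = _cohort_table(21)
    model = fit_ps_logistic(t[[*PS_COVARIATES, "sb_pre"]],
                            t["z"].to_numpy(dtype=float))
    worst = assert_exact_balance(model, tol=1e-8)
    assert worst < 1e-8


def test_weighting_reduces_age_imbalance():
    t = _cohort_table(22)
    model = fit_ps_logistic(t[[*PS_COVARIATES, "sb_pre"]],
                            t["z"].to_numpy(dtype=float))
    ow = compute_overlap_weights(model)
    bal = balance_diagnostics(t[[*PS_COVARIATES, "sb_pre"]], ow).set_index("covariate")
    assert abs(bal.loc["age", "smd_unweighted"]) > abs(bal.loc["age", "smd_weighted"])
    assert abs(bal.loc["age", "smd_unweighted"]) > 0.3  # confounding is real


def test_identical_distributions_unit_weights_zero_smd(rng):
    x = pd.DataFrame({"a": np.tile(rng.normal(0, 1, 50), 2)})
    z = np.repeat([1.0, 0.0], 50)
    ow = OverlapWeights(weights=np.ones(100), z=z, ps=np.full(100, 0.5))
    bal = balance_diagnostics(x, ow)
    assert bal["smd_unweighted"].abs().max() < 1e-12


# ---------------------------------------------------------------------------
# estimator calibration (Monte Carlo)

def test_group_difference_consistent_over_replicates():
    """Mean estimated group difference across 100 cohorts is within 2 MC SEs
    of the programmed effect (work engagement: measured without device noise,
    negligible scale-discretization)."""
    from actibreak.pipeline import analyze_outcome
    diffs = []
    for seed in range(1, 101):
        cfg = CohortConfig(seed=seed, wear_days_override=5,
                           missingness=no_missingness())
        cohort = simulate_cohort(cfg, mode="tabular", seed=seed)
        t = build_analysis_table(cohort, ())
        need = ["z", *PS_COVARIATES, "uwes_pre", "uwes_post"]
        d, _, _ = analyze_outcome([t[need].dropna()], "uwes")
        diffs.append(d.estimate)
    diffs = np.array(diffs)
    truth = -0.2
    mc_se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - truth) < 2 * mc_se


def test_ci_coverage_between_92_and_98_percent():
    """Empirical coverage of the programmed group difference by the 95%
    sandwich CI over 500 fast replicates."""
    from actibreak.pipeline import analyze_outcome
    covered = 0
    for seed in range(1, 501):
        cfg = CohortConfig(seed=seed, wear_days_override=5,
                           missingness=no_missingness())
        cohort = simulate_cohort(cfg, mode="tabular", seed=seed)
        t = build_analysis_table(cohort, ())
        need = ["z", *PS_COVARIATES, "uwes_pre", "uwes_post"]
        d, _, _ = analyze_outcome([t[need].dropna()], "uwes")
        covered += d.ci_low <= -0.2 <= d.ci_high
    assert 0.92 <= covered / 500 <= 0.98
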