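"""Generator contracts: assignment, chains, outcomes, missingness, adherence."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from actibreak.config import (ADHERENCE_LEVELS, ArmProfile, CohortConfig,
                              MissingnessConfig,
                              default_control_profile,
                              default_intervention_profile)
from actibreak import synthetic as syn
from tests.conftest import no_missingness


# ---------------------------------------------------------------------------
# covariates / assignment

def test_exact_arm_sizes_tiny_cohort():
    cfg = CohortConfig()
    cfg.intervention.n = 2
    cfg.control.n = 2
    subj = syn.generate_covariates(cfg, np.random.default_rng(0))
    assert len(subj) == 4
    assert subj["z"].sum() == 2


def test_nonpositive_arm_size_rejected():
    prof = default_intervention_profile()
    with pytest.raises(ValueError):
        ArmProfile(**{**prof.__dict__, "n": 1})


def test_intervention_mean_age_calibrated_over_reps():
    ages = []
    for seed in range(50):
        subj = syn.generate_covariates(CohortConfig(seed=seed))
        ages.append(subj.loc[subj["z"] == 1, "age"].mean())
    assert abs(np.mean(ages) - 45.3) < 1.0


def test_zero_confounding_makes_arms_exchangeable():
    cfg = CohortConfig(confounding=0.0)
    means = {"intervention": [], "control": []}
    for seed in range(30):
        subj = syn.generate_covariates(cfg, np.random.default_rng(seed))
        for arm in means:
            sel = subj["group"] == arm
            means[arm].append([subj.loc[sel, "age"].mean(),
                               subj.loc[sel, "female"].mean(),
                               subj.loc[sel, "bmi"].mean()])
    gap = np.abs(np.mean(means["intervention"], axis=0)
                 - np.mean(means["control"], axis=0))
    assert np.all(gap < np.array([0.5, 0.03, 0.2]))


# ---------------------------------------------------------------------------
# Markov machinery

def test_transition_matrix_stationary_matches_eigendecomposition():
    pi = np.array([0.08, 0.59, 0.29, 0.04])
    P = syn.transition_matrix(pi, np.array([150.0, 10.0, 6.5, 5.0]))
    np.testing.assert_allclose(syn.stationary_distribution(P), pi, atol=1e-9)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(P >= 0)


def test_empirical_occupancy_within_one_percent_at_1e5_epochs():
    pi = np.array([0.08, 0.59, 0.29, 0.04])
    P = syn.transition_matrix(pi, np.array([20.0, 10.0, 6.5, 5.0]))
    n = 100_000
    rng = np.random.default_rng(7)
    states = syn._simulate_chains(P[None], pi[None], n, rng)[0]
    occ = np.bincount(states, minlength=4) / n
    assert np.all(np.abs(occ - pi) < 0.01)


def test_degenerate_all_sb_profile():
    """A profile that is pure SB with no non-wear yields only SB epochs."""
    cfg = CohortConfig(seed=0)
    row = pd.Series({"worker_id": "W0", "group": "intervention",
                     "target_sb": 480.0, "target_lpa": 0.0,
                     "target_mvpa": 0.0, "nonwear_frac": 0.0})
    frame = syn.generate_epoch_stream(row, cfg, "pre",
                                      np.random.default_rng(3), n_days=2)
    assert len(frame) == 960
    assert ((frame["met"] > 0) & (frame["met"] <= 1.5)).all()


def test_epoch_frame_layout_and_half_open_window():
    cfg = CohortConfig(seed=0)
    row = pd.Series({"worker_id": "W9", "group": "control"})
    frame = syn.generate_epoch_stream(row, cfg, "pre",
                                      np.random.default_rng(1), n_days=1)
    assert list(frame.columns) == ["worker_id", "date", "time", "met", "steps"]
    assert len(frame) == 480
    assert frame["time"].iloc[0] == "09:00:00"
    assert frame["time"].iloc[-1] == "16:59:00"
    assert (frame["met"] >= 0).all() and (frame["steps"] >= 0).all()


def test_met_values_respect_state_ranges():
    cfg = CohortConfig(seed=0)
    row = pd.Series({"worker_id": "W1", "group": "intervention"})
    frame = syn.generate_epoch_stream(row, cfg, "pre",
                                      np.random.default_rng(5), n_days=5)
    met = frame["met"].to_numpy()
    nonzero = met[met > 0]
    # 0.1 MET resolution
    np.testing.assert_allclose(np.round(met * 10) / 10, met, atol=1e-12)
    assert nonzero.min() >= 0.9


# ---------------------------------------------------------------------------
# outcomes

def test_zero_effect_zero_noise_scores_identical_across_visits():
    cfg = CohortConfig(seed=3, missingness=no_missingness())
    for prof in (cfg.intervention, cfg.control):
        prof.k6_change = prof.uwes_change = prof.hpq_change = 0.0
        prof.k6_change_sd = prof.uwes_change_sd = prof.hpq_change_sd = 0.0
    subj = syn.generate_covariates(cfg, np.random.default_rng(0))
    out = syn.generate_outcomes(subj, cfg, np.random.default_rng(1))
    for scale, n_items in (("k6", 6), ("uwes", 9)):
        pre = out[[f"{scale}_item{i}_pre" for i in range(1, n_items + 1)]]
        post = out[[f"{scale}_item{i}_post" for i in range(1, n_items + 1)]]
        np.testing.assert_array_equal(pre.to_numpy(), post.to_numpy())
    np.testing.assert_array_equal(out["hpq_pre"], out["hpq_post"])


def test_programmed_k6_change_recovered_in_arm_means():
    diffs = []
    for seed in range(12):
        cfg = CohortConfig(seed=seed, missingness=no_missingness())
        subj = syn.generate_covariates(cfg, np.random.default_rng(seed))
        out = syn.generate_outcomes(subj, cfg, np.random.default_rng(seed + 100))
        k6_pre = out[[f"k6_item{i}_pre" for i in range(1, 7)]].sum(axis=1)
        k6_post = out[[f"k6_item{i}_post" for i in range(1, 7)]].sum(axis=1)
        diffs.append((k6_post - k6_pre)[out["z"] == 1].mean())
    assert abs(np.mean(diffs) - 1.6) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.05


def test_latent_calibration_inverts_observation_map():
    mu = syn.calibrate_latent_mean(5.1, 5.2, lo=0, hi=24, step=1)
    draws = syn.observe_score(np.random.default_rng(0).normal(mu, 5.2, 400_000),
                              lo=0, hi=24, step=1)
    assert abs(draws.mean() - 5.1) < 0.03


# ---------------------------------------------------------------------------
# missingness

def test_zero_rates_leave_tables_untouched():
    cfg = CohortConfig(seed=5, missingness=no_missingness(),
                       wear_days_override=5)
    cohort = syn.simulate_cohort(cfg, mode="tabular", seed=5)
    assert cohort.missing_report[["n_missing_intervention",
                                  "n_missing_control"]].to_numpy().sum() == 0
    item_cols = [c for c in cohort.subjects.columns if "item" in c]
    assert not cohort.subjects[item_cols].isna().any().any()


def test_rate_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        MissingnessConfig(accel=(1.2, 0.0))


def test_default_accel_missing_counts_match_study_pattern():
    """Device dropouts plus the >=4-valid-day rule reproduce the published
    missing-count pattern (28 of 172 intervention, 17 of 323 control)."""
    from actibreak.pipeline import build_analysis_table
    counts = []
    for seed in (7, 8, 9):
        cohort = syn.simulate_cohort(CohortConfig(seed=seed), mode="full",
                                     seed=seed)
        t = build_analysis_table(cohort, ("sb",))
        counts.append([int(t.loc[t.z == 1, "sb_pre"].isna().sum()),
                       int(t.loc[t.z == 0, "sb_pre"].isna().sum())])
    mean = np.mean(counts, axis=0)
    assert 18 <= mean[0] <= 40
    assert 8 <= mean[1] <= 28


def test_mar_refit_recovers_programmed_slope():
    """Logistic refit of the dropout indicator on age recovers the programmed
    MAR coefficient; given age, missingness ignores the unobserved value."""
    cfg = CohortConfig(seed=1)
    cfg.intervention.n = 8000
    cfg.control.n = 100
    cfg.missingness = MissingnessConfig(accel=(0.3, 0.0), mar_slope_accel=0.5)
    subj = syn.generate_covariates(cfg, np.random.default_rng(2))
    ind = syn.draw_missingness(subj, cfg, np.random.default_rng(3))
    sel = (subj["group"] == "intervention").to_numpy()
    age = subj.loc[sel, "age"].to_numpy()
    zage = (age - age.mean()) / age.std()
    y = ind.loc[sel, "accel"].to_numpy().astype(float)
    res = sm.Logit(y, sm.add_constant(zage)).fit(disp=0)
    assert abs(res.params[1] - 0.5) < 3 * res.bse[1]


# ---------------------------------------------------------------------------
# adherence

def test_adherence_bad_probabilities_rejected():
    with pytest.raises(ValueError):
        CohortConfig(adherence_probs={"t0": (0.5, 0.5, 0.5, 0.5),
                                      "m6": (0.25,) * 4, "m12": (0.25,) * 4})


def test_adherence_degenerate_probabilities_give_identical_responses():
    cfg = CohortConfig(adherence_probs={t: (1.0, 0.0, 0.0, 0.0)
                                        for t in ("t0", "m6", "m12")})
    subj = syn.generate_covariates(cfg, np.random.default_rng(0))
    out = syn.generate_adherence(subj, cfg, np.random.default_rng(1))
    vals = out.loc[out["z"] == 1, "adherence_t0"]
    assert (vals == "almost_never").all()


def test_adherence_shares_converge_to_configured_probabilities():
    cfg = CohortConfig()
    cfg.intervention.n = 10_000
    subj = syn.generate_covariates(cfg, np.random.default_rng(0))
    out = syn.generate_adherence(subj, cfg, np.random.default_rng(1))
    shares = out.loc[out["z"] == 1, "adherence_m12"].value_counts(normalize=True)
    for level, p in zip(ADHERENCE_LEVELS, cfg.adherence_probs["m12"]):
        assert abs(shares.get(level, 0.0) - p) < 0.02


def test_adherence_requires_intervention_arm():
    cfg = CohortConfig()
    subj = syn.generate_covariates(cfg, np.random.default_rng(0))
    with pytest.raises(ValueError):
        syn.generate_adherence(subj[subj["z"] == 0], cfg)


# ---------------------------------------------------------------------------
# whole-cohort invariants

def test_simulate_cohort_is_deterministic_per_seed(clean_cohort_config):
    a = syn.simulate_cohort(clean_cohort_config, mode="full", seed=99)
    b = syn.simulate_cohort(clean_cohort_config, mode="full", seed=99)
    pd.testing.assert_frame_equal(a.subjects, b.subjects)
    np.testing.assert_array_equal(a.epochs["pre"].met, b.epochs["pre"].met)
    np.testing.assert_array_equal(a.epochs["post"].steps, b.epochs["post"].steps)


def test_latent_behavior_targets_sum_to_480(clean_cohort_config):
    cohort = syn.simulate_cohort(clean_cohort_config, mode="tabular", seed=4)
    for visit in ("pre", "post"):
        np.testing.assert_allclose(cohort.latent_behavior[visit].sum(axis=1),
                                   480.0, atol=1e-9)


def test_true_effects_group_difference_identity():
    eff = syn.TrueEffects.from_config(CohortConfig())
    for o in ("sb", "lpa", "mvpa", "k6", "uwes", "hpq"):
        assert eff.group_difference(o) == pytest.approx(
            eff.intervention[o] - eff.control[o])
    # behavior changes respect the compositional zero-sum constraint
    for arm in (eff.intervention, eff.control):
        assert arm["sb"] + arm["lpa"] + arm["mvpa"] == pytest.approx(0.0, abs=1e-9)
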