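"""End-to-end study orchestration.

simulate -> process epochs -> score questionnaires -> impute (m chained-PMM
datasets) -> per-dataset propensity/overlap/ATO with sandwich variance ->
Rubin pooling -> report.  Also produces the baseline characteristics table
(Welch t / chi-square two-group tests), the complete-case sensitivity
analysis, the adherence summary, and balance diagnostics.  Everything is a
pure function of the configuration and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import accelerometry as accel
from . import questionnaires as quest
from .causal import (assert_exact_balance, ato_inference, balance_diagnostics,
                     compute_overlap_weights, fit_ps_logistic)
from .config import (ACCEL_OUTCOMES, QUESTIONNAIRE_OUTCOMES, StudyConfig)
from .imputation import PooledEstimate, impute_pmm, pool_rubin
from .synthetic import Cohort, simulate_cohort

PS_COVARIATES = ["age", "female", "bmi", "manager"]


def process_cohort_epochs(cohort: Cohort, visit: str) -> pd.DataFrame:
    """Run the device pipeline on one visit's epoch batch.

    Returns one row per subject with standardized behavior metrics (NaN for
    subjects below 4 valid days or without device data).
    """
    batch = cohort.epochs[visit]
    if batch is None:
        raise ValueError("cohort has no epoch streams (tabular mode?)")
    daily = accel.process_days(batch.met, batch.steps)
    daily["worker_id"] = cohort.subjects["worker_id"].to_numpy()[batch.subject_idx]
    summary = accel.summarize_subjects(daily)
    return summary


def build_analysis_table(cohort: Cohort, outcomes) -> pd.DataFrame:
    """Assemble the subject-level analysis table for the requested outcomes."""
    table = quest.score_subject_frame(cohort.subjects)
    keep = ["worker_id", "group", "z", *PS_COVARIATES]
    keep += [c for c in table.columns if c.startswith("adherence_")]
    for q in QUESTIONNAIRE_OUTCOMES:
        keep += [f"{q}_pre", f"{q}_post"]
    table = table[keep].copy()

    accel_wanted = [o for o in outcomes if o in ACCEL_OUTCOMES]
    if cohort.mode == "full":
        for visit in ("pre", "post"):
            summ = process_cohort_epochs(cohort, visit)
            cols = {o: f"{o}_{visit}" for o in ACCEL_OUTCOMES}
            renamed = summ.rename(columns=cols)
            extra = [f"{o}_{visit}" for o in ACCEL_OUTCOMES]
            extra += []
            merged = renamed[["worker_id", *extra]].copy()
            merged[f"weartime_{visit}"] = summ["weartime"].to_numpy()
            merged[f"n_valid_days_{visit}"] = summ["n_valid_days"].to_numpy()
            table = table.merge(merged, on="worker_id", how="left")
    else:
        missing_accel = [o for o in accel_wanted if f"{o}_pre" not in cohort.subjects]
        if missing_accel:
            raise ValueError(
                f"tabular mode provides sb/lpa/mvpa only; cannot analyze {missing_accel}")
        for o in ("sb", "lpa", "mvpa"):
            if f"{o}_pre" in cohort.subjects:
                table[f"{o}_pre"] = cohort.subjects[f"{o}_pre"].to_numpy()
                table[f"{o}_post"] = cohort.subjects[f"{o}_post"].to_numpy()
    return table


@dataclass
class OutcomeResult:
    """Pooled results-table row for one outcome."""

    outcome: str
    n_analyzed: int
    pre_mean: dict
    pre_sd: dict
    post_mean: dict
    post_sd: dict
    change_treated: PooledEstimate
    change_control: PooledEstimate
    difference: PooledEstimate


def analyze_outcome(datasets: list[pd.DataFrame], outcome: str,
                    sandwich: str = "stacked",
                    check_balance: bool = True) -> tuple[PooledEstimate, PooledEstimate, PooledEstimate]:
    """Per-imputation ATO estimation and Rubin pooling for one outcome.

    Each imputed dataset gets its own propensity model (covariates plus the
    outcome's baseline value), overlap weights, Hajek within-arm mean changes
    and contrast, and stacked-sandwich variances; estimates are pooled by
    Rubin's rules.  Returns (difference, treated change, control change).
    """
    diffs, vdiffs = [], []
    mus1, v1s, mus0, v0s = [], [], [], []
    for df in datasets:
        X = df[[*PS_COVARIATES, f"{outcome}_pre"]]
        z = df["z"].to_numpy(dtype=float)
        y = (df[f"{outcome}_post"] - df[f"{outcome}_pre"]).to_numpy(dtype=float)
        model = fit_ps_logistic(X, z)
        if check_balance:
            assert_exact_balance(model, tol=1e-6)
        est = ato_inference(model, y, method=sandwich)
        diffs.append(est.diff)
        vdiffs.append(est.se ** 2)
        mus1.append(est.mean_treated)
        v1s.append(est.se_treated ** 2)
        mus0.append(est.mean_control)
        v0s.append(est.se_control ** 2)
    if len(datasets) == 1:
        # complete-case single fit: wrap as a degenerate pool
        z95 = stats.norm.ppf(0.975)

        def _single(q, v):
            se = float(np.sqrt(v))
            p = 2.0 * stats.norm.sf(abs(q) / se) if se > 0 else 1.0
            return PooledEstimate(estimate=q, se=se, W=v, B=0.0, T=v,
                                  df=np.inf, ci_low=q - z95 * se,
                                  ci_high=q + z95 * se, p=p, m=1)
        return (_single(diffs[0], vdiffs[0]), _single(mus1[0], v1s[0]),
                _single(mus0[0], v0s[0]))
    return (pool_rubin(diffs, vdiffs), pool_rubin(mus1, v1s),
            pool_rubin(mus0, v0s))


def _observed_descriptives(table: pd.DataFrame, outcome: str) -> dict:
    out = {}
    for visit in ("pre", "post"):
        col = f"{outcome}_{visit}"
        for arm in ("intervention", "control"):
            vals = table.loc[table["group"] == arm, col]
            out[f"{visit}_{arm}_mean"] = float(vals.mean())
            out[f"{visit}_{arm}_sd"] = float(vals.std(ddof=1))
    return out


_BASELINE_CONTINUOUS = [
    ("age", "Age (years)"),
    ("bmi", "Body mass index (kg/m^2)"),
    ("n_valid_days_pre", "Wearing days (days)"),
    ("weartime_pre", "Weartime (min/8 hrs)"),
    ("sb_pre", "SB (min/8 hrs)"),
    ("prolonged_sb_min_pre", "Prolonged SB (min/8 hrs)"),
    ("prolonged_sb_count_pre", "Prolonged SB (counts/8 hrs)"),
    ("lpa_pre", "LPA (min/8 hrs)"),
    ("mvpa_pre", "MVPA (min/8 hrs)"),
    ("bouted_pa_min_pre", "Bouted PA (min/8 hrs)"),
    ("bouted_pa_count_pre", "Bouted PA (counts/8 hrs)"),
    ("steps_pre", "Step count (steps/8 hrs)"),
    ("k6_pre", "Psychological distress (points)"),
    ("uwes_pre", "Work engagement (points)"),
    ("hpq_pre", "Job performance (points)"),
]
_BASELINE_BINARY = [("female", "Women"), ("manager", "Manager")]


def baseline_table(table: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics with two-group tests.

    Continuous variables: arm mean (SD) and Welch (unequal-variance) t-test;
    binary variables: count (%) and Pearson chi-square; per-arm missing
    counts are reported for every variable.
    """
    z = table["z"].to_numpy(dtype=int)
    rows = []

    def _row(label, col, kind):
        x = table[col].to_numpy(dtype=float)
        r = {"variable": label}
        for arm, sel in (("intervention", z == 1), ("control", z == 0)):
            v = x[sel]
            obs = v[~np.isnan(v)]
            if kind == "continuous":
                r[f"{arm}_mean"] = float(obs.mean()) if obs.size else np.nan
                r[f"{arm}_sd"] = float(obs.std(ddof=1)) if obs.size > 1 else np.nan
            else:
                r[f"{arm}_n"] = int(obs.sum())
                r[f"{arm}_pct"] = 100.0 * obs.mean() if obs.size else np.nan
            r[f"{arm}_missing"] = int(np.isnan(v).sum())
        a = x[(z == 1) & ~np.isnan(x)]
        b = x[(z == 0) & ~np.isnan(x)]
        if a.size < 2 or b.size < 2:
            r["p"] = np.nan
            r["note"] = "insufficient observed data in an arm"
        elif kind == "continuous":
            r["p"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            contingency = np.array([[a.sum(), a.size - a.sum()],
                                    [b.sum(), b.size - b.sum()]])
            r["p"] = float(stats.chi2_contingency(contingency)[1])
        return r

    for col, label in _BASELINE_BINARY:
        if col in table:
            rows.append(_row(label, col, "binary"))
    for col, label in _BASELINE_CONTINUOUS:
        if col in table:
            rows.append(_row(label, col, "continuous"))
    return pd.DataFrame(rows)


@dataclass
class StudyReport:
    """All study outputs, traceable to one seed."""

    baseline: pd.DataFrame
    results: pd.DataFrame
    results_complete_case: pd.DataFrame | None
    adherence: pd.DataFrame
    balance: pd.DataFrame
    missing_report: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _results_frame(table, datasets, outcomes, sandwich) -> pd.DataFrame:
    rows = []
    for outcome in outcomes:
        desc = _observed_descriptives(table, outcome)
        diff, mu1, mu0 = analyze_outcome(datasets, outcome, sandwich=sandwich)
        rows.append({
            "outcome": outcome,
            **desc,
            "change_intervention": mu1.estimate,
            "change_intervention_ci_low": mu1.ci_low,
            "change_intervention_ci_high": mu1.ci_high,
            "change_control": mu0.estimate,
            "change_control_ci_low": mu0.ci_low,
            "change_control_ci_high": mu0.ci_high,
            "group_difference": diff.estimate,
            "group_difference_ci_low": diff.ci_low,
            "group_difference_ci_high": diff.ci_high,
            "group_difference_se": diff.se,
            "p": diff.p,
            "m": diff.m,
        })
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full study and return its report (deterministic per seed)."""
    cohort = simulate_cohort(config.cohort, mode="full", seed=config.seed)
    return analyze_cohort(cohort, config)


def analyze_cohort(cohort: Cohort, config: StudyConfig) -> StudyReport:
    """Score, impute and estimate on an already simulated cohort."""
    table = build_analysis_table(cohort, config.outcomes)
    base = baseline_table(table)
    adherence = quest.summarize_adherence(
        table.loc[table["group"] == "intervention"])

    impute_cols = [*PS_COVARIATES]
    for o in config.outcomes:
        impute_cols += [f"{o}_pre", f"{o}_post"]
    mi_input = table[["z", *impute_cols]].copy()
    spec = config.imputation
    spec = type(spec)(m=spec.m, n_iterations=spec.n_iterations,
                      k_donors=spec.k_donors, seed=config.seed + 1)
    # standardized behavior minutes are compositional (sum to 480/day), so
    # each accelerometer variable's equation conditions only on its own
    # other-visit value plus the non-accelerometer predictors
    accel_cols = {f"{o}_{v}" for o in ACCEL_OUTCOMES for v in ("pre", "post")}
    non_accel = [c for c in ("z", *impute_cols) if c not in accel_cols]
    predictor_map = {}
    for o in config.outcomes:
        if o in ACCEL_OUTCOMES:
            for v in ("pre", "post"):
                partner = f"{o}_post" if v == "pre" else f"{o}_pre"
                predictor_map[f"{o}_{v}"] = [*non_accel, partner]
    datasets = impute_pmm(mi_input, spec, columns=impute_cols,
                          predictor_map=predictor_map)
    results = _results_frame(table, datasets, config.outcomes, config.sandwich)

    results_cc = None
    if config.complete_case:
        rows_cc = []
        for outcome in config.outcomes:
            need = ["z", *PS_COVARIATES, f"{outcome}_pre", f"{outcome}_post"]
            cc = table[need].dropna()
            rows_cc.append((outcome, cc))
        frames = []
        for outcome, cc in rows_cc:
            diff, mu1, mu0 = analyze_outcome([cc], outcome,
                                             sandwich=config.sandwich)
            frames.append({
                "outcome": outcome, "n": len(cc),
                "change_intervention": mu1.estimate,
                "change_control": mu0.estimate,
                "group_difference": diff.estimate,
                "group_difference_ci_low": diff.ci_low,
                "group_difference_ci_high": diff.ci_high,
                "p": diff.p,
            })
        results_cc = pd.DataFrame(frames)

    # balance diagnostics from the first imputed dataset, first outcome
    first = datasets[0]
    o0 = config.outcomes[0]
    model = fit_ps_logistic(first[[*PS_COVARIATES, f"{o0}_pre"]],
                            first["z"].to_numpy(dtype=float))
    ow = compute_overlap_weights(model)
    balance = balance_diagnostics(first[[*PS_COVARIATES, f"{o0}_pre"]], ow)

    metadata = {"seed": config.seed, "n_intervention": int(table["z"].sum()),
                "n_control": int((1 - table["z"]).sum()),
                "m": config.imputation.m, "outcomes": list(config.outcomes),
                "mode": cohort.mode}
    return StudyReport(baseline=base, results=results,
                       results_complete_case=results_cc, adherence=adherence,
                       balance=balance, missing_report=cohort.missing_report,
                       metadata=metadata)
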