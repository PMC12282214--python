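"""Synthetic two-arm cohort generator.

Emulates the study's inputs end to end so every downstream stage can be
exercised without participant data: confounded assignment to a 172-worker
intervention arm and a 323-worker control arm (controls older, more male,
more managerial, more sedentary), epoch-level accelerometer streams over the
09:00-17:00 work window, questionnaire item responses at baseline and
one-year follow-up, program-adherence recalls, and MAR missingness matching
the published per-variable missing counts.

Generative model
----------------
* Covariates are drawn arm-conditionally from the published baseline
  distributions; because both arms come from exponential-family conditionals,
  the implied true propensity score is logistic-family in the covariates.
  A scalar ``confounding`` knob interpolates arm parameters toward the pooled
  values (0 = exchangeable arms).
* Each subject-visit has latent standardized behavior targets
  (SB, LPA, MVPA minutes per 8-hour day) that sum to exactly 480: deviations
  are built on a zero-sum basis with the published between-subject SDs, the
  MVPA deviation using a centered gamma so MVPA stays positive without
  mean-biasing clamps.  Follow-up deviations are a random walk from baseline
  (an independent zero-sum increment with the published change-score SDs),
  so change scores are mean-independent of baseline and the arm-level true
  changes added at follow-up remain the estimand under any propensity
  weighting.
* Epoch streams are first-order Markov chains over {non-wear, SB, LPA, MVPA}
  whose stationary occupancy equals the subject's target profile, built by
  the sticky-jump construction (stationarity is exact by algebra for any
  dwell times).  MET per epoch: 0 for non-wear, uniform 0.9-1.5 for SB,
  uniform 1.6-2.9 for LPA, 3.0 + Exp(0.5) for MVPA, at 0.1 MET resolution;
  steps are Poisson with intensity proportional to MET during activity.
* Questionnaire scores are observed through round-and-clamp onto each
  scale's grid; latent means are calibrated by numerically inverting the
  observation map so arm means and changes equal the programmed values
  despite floor effects, then decomposed into items that re-score exactly.
* Missingness is MAR: device dropouts follow a logistic model in age with
  an intercept solved to hit the arm's target rate; questionnaire and
  covariate missingness use the published per-variable rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import (ADHERENCE_LEVELS, ADHERENCE_TIMES, WORKDAY_MIN,
                     ArmProfile, CohortConfig)
from .questionnaires import K6_N_ITEMS, UWES_DEFAULT_N_ITEMS

STATES = ("nonwear", "sb", "lpa", "mvpa")
VISITS = ("pre", "post")

# ---------------------------------------------------------------------------
# Markov machinery


def transition_matrix(pi: np.ndarray, dwell: np.ndarray) -> np.ndarray:
    """Transition matrix with stationary ``pi`` and mean run lengths ``dwell``.

    Diagonal entries are the stay probabilities 1 - 1/t_s; off-diagonal mass
    follows a zero-diagonal jump chain Q whose stationary distribution is the
    leave-flow law nu ~ pi_s / t_s, so that occupancy is exactly ``pi`` and
    runs of state s are geometric with mean t_s.  Q is built by iterative
    proportional fitting of a flow matrix to margins nu with a zero diagonal,
    which is feasible whenever max(nu) <= 1/2; dwell requests violating that
    bound (a state so dominant it cannot be left that often) are relaxed by
    lengthening the dominant state's dwell to the feasibility boundary.
    """
    pi = np.asarray(pi, dtype=float)
    dwell = np.asarray(dwell, dtype=float)
    if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi must be a probability vector")
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    k = len(pi)
    active = np.flatnonzero(pi > 1e-12)
    if active.size == 1:
        P = np.zeros((k, k))
        P[:, active[0]] = 1.0
        return P

    t = np.maximum(dwell[active].astype(float), 1.0)
    p = pi[active]
    f = p / t
    # feasibility: the dominant state's leave flow cannot exceed the others'.
    # First shorten the other states' dwells (dominant-state run structure is
    # the calibrated quantity; floor 2 min), then as a last resort lengthen
    # the dominant state's dwell to the boundary.
    m = int(np.argmax(f))
    slack = 1.0 if active.size == 2 else 0.499 / 0.501
    other = float(f.sum() - f[m])
    if f[m] > other * slack:
        shrink = f[m] / (other * slack)
        rest = np.arange(active.size) != m
        t[rest] = np.maximum(t[rest] / shrink, 2.0)
        f = p / t
        other = float(f.sum() - f[m])
        if f[m] > other * slack:
            f[m] = other * slack
            t[m] = p[m] / f[m]
    nu = f / f.sum()

    # IPF: zero-diagonal flow matrix with row and column margins nu
    M = np.outer(nu, nu)
    np.fill_diagonal(M, 0.0)
    for _ in range(100_000):
        M *= (nu / M.sum(axis=1))[:, None]
        colsum = M.sum(axis=0)
        err = np.max(np.abs(colsum - nu))
        M *= (nu / colsum)[None, :]
        if err < 1e-14:
            break
    Q = M / M.sum(axis=1, keepdims=True)

    P = np.zeros((k, k))
    sub = np.eye(active.size) * (1.0 - 1.0 / t) + (1.0 / t)[:, None] * Q
    P[np.ix_(active, active)] = sub
    # unoccupied states (never entered) jump straight to the flow law
    inactive = np.setdiff1d(np.arange(k), active)
    for s in inactive:
        P[s, active] = nu
    return P


def _transition_matrices(pis: np.ndarray, dwells: np.ndarray) -> np.ndarray:
    """Batched :func:`transition_matrix` for strictly positive profiles.

    Same construction (diagonal stay probabilities + IPF-fitted zero-diagonal
    jump chain), vectorized over the leading axis.
    """
    p = np.clip(np.asarray(pis, dtype=float), 1e-9, None)
    p = p / p.sum(axis=1, keepdims=True)
    n, k = p.shape
    t = np.maximum(np.asarray(dwells, dtype=float), 1.0).copy()
    f = p / t
    # dominant-state feasibility: shorten the other states' dwells first
    m = np.argmax(f, axis=1)
    rows = np.arange(n)
    fm = f[rows, m]
    other = f.sum(axis=1) - fm
    slack = 0.499 / 0.501
    shrink = fm / (other * slack)
    need = shrink > 1.0
    if need.any():
        factor = np.where(need, shrink, 1.0)
        t_new = np.maximum(t / factor[:, None], 2.0)
        t_new[rows, m] = t[rows, m]
        t = t_new
        f = p / t
        fm = f[rows, m]
        other = f.sum(axis=1) - fm
        cap = other * slack
        over = fm > cap
        fm_new = np.where(over, cap, fm)
        t[rows, m] = np.where(over, p[rows, m] / fm_new, t[rows, m])
        f[rows, m] = fm_new
    nu = f / f.sum(axis=1, keepdims=True)

    M = nu[:, :, None] * nu[:, None, :]
    diag = np.arange(k)
    M[:, diag, diag] = 0.0
    for _ in range(600):
        M *= (nu / M.sum(axis=2))[:, :, None]
        M *= (nu / M.sum(axis=1))[:, None, :]
    Q = M / M.sum(axis=2, keepdims=True)
    inv_t = 1.0 / t
    P = Q * inv_t[:, :, None]
    P[:, diag, diag] += 1.0 - inv_t
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a transition matrix via eigen-decomposition."""
    vals, vecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _simulate_chains(P_cube: np.ndarray, pi_mat: np.ndarray, n_steps: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Simulate one Markov path per row; initial states from each row's pi."""
    n = P_cube.shape[0]
    cum0 = np.cumsum(pi_mat, axis=1)
    states = np.empty((n, n_steps), dtype=np.int8)
    u = rng.random(n)
    states[:, 0] = (u[:, None] > cum0).sum(axis=1)
    cum = np.cumsum(P_cube, axis=2)
    rows = np.arange(n)
    for t in range(1, n_steps):
        c = cum[rows, states[:, t - 1]]
        u = rng.random(n)
        states[:, t] = (u[:, None] > c).sum(axis=1)
    return states


def _met_for_states(states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """MET values per epoch given chain states, at 0.1 MET resolution."""
    met = np.zeros(states.shape, dtype=float)
    sb = states == 1
    lpa = states == 2
    mvpa = states == 3
    met[sb] = rng.uniform(0.9, 1.5, size=int(sb.sum()))
    met[lpa] = rng.uniform(1.6, 2.9, size=int(lpa.sum()))
    met[mvpa] = 3.0 + rng.exponential(0.5, size=int(mvpa.sum()))
    return np.round(met, 1)


# ---------------------------------------------------------------------------
# latent-score calibration for the questionnaire scales


def observe_score(latent, lo: float, hi: float, step: float):
    """Round a latent value onto the scale grid and clamp to the range."""
    snapped = np.round(np.asarray(latent, dtype=float) / step) * step
    return np.clip(snapped, lo, hi)


def _expected_observed(mu: float, sd: float, lo: float, hi: float,
                       step: float) -> float:
    levels = np.round(np.arange(lo, hi + step / 2, step) / step) * step
    edges = np.concatenate(([-np.inf], (levels[:-1] + levels[1:]) / 2, [np.inf]))
    probs = np.diff(stats.norm.cdf(edges, loc=mu, scale=sd))
    return float(np.sum(levels * probs))


def calibrate_latent_mean(target: float, sd: float, lo: float, hi: float,
                          step: float) -> float:
    """Latent mean whose round-and-clamp observation has mean ``target``."""
    if not lo <= target <= hi:
        raise ValueError("target score outside the scale range")
    f = lambda mu: _expected_observed(mu, sd, lo, hi, step) - target
    return float(optimize.brentq(f, lo - 6 * sd, hi + 6 * sd, xtol=1e-10))


def decompose_k6(total: int) -> np.ndarray:
    """Split a 0-24 K6 total into six 0-4 items that sum back exactly."""
    total = int(total)
    if not 0 <= total <= 24:
        raise ValueError("K6 total outside 0-24")
    q, r = divmod(total, K6_N_ITEMS)
    return np.array([q + 1] * r + [q] * (K6_N_ITEMS - r))


def decompose_uwes(mean_score: float, n_items: int = UWES_DEFAULT_N_ITEMS) -> np.ndarray:
    """Split a 0-6 engagement mean (on the 1/n grid) into 0-6 items."""
    total = int(round(mean_score * n_items))
    if not 0 <= total <= 6 * n_items:
        raise ValueError("engagement score outside 0-6")
    q, r = divmod(total, n_items)
    return np.array([q + 1] * r + [q] * (n_items - r))


# ---------------------------------------------------------------------------
# configuration helpers


def _interp_profile(cfg: CohortConfig, arm: str) -> ArmProfile:
    """Arm profile with confounded parameters shrunk toward the pooled values."""
    c = cfg.confounding
    own = cfg.intervention if arm == "intervention" else cfg.control
    other = cfg.control if arm == "intervention" else cfg.intervention
    if c == 1.0:
        return own
    w_own = own.n / (own.n + other.n)
    mix = {}
    pooled_fields = ("age_mean", "age_sd", "p_female", "bmi_mean", "bmi_sd",
                     "p_manager", "behavior_mean", "behavior_sd",
                     "nonwear_frac_mean", "nonwear_frac_sd", "dwell",
                     "step_rate", "k6", "uwes", "hpq")
    for name in pooled_fields:
        a = np.asarray(getattr(own, name), dtype=float)
        b = np.asarray(getattr(other, name), dtype=float)
        pooled = w_own * a + (1.0 - w_own) * b
        v = pooled + c * (a - pooled)
        mix[name] = tuple(v.tolist()) if v.ndim else float(v)
    out = {**own.__dict__, **mix}
    return ArmProfile(**out)


@dataclass
class TrueEffects:
    """Programmed estimands: per-arm mean changes and their group differences.

    Behavior changes are on the standardized min/8-hrs scale after zero-sum
    adjustment (standardized minutes are compositional), questionnaire changes
    on native scales.  These are the values the recovery harness targets.
    """

    intervention: dict = field(default_factory=dict)
    control: dict = field(default_factory=dict)

    @classmethod
    def from_config(cls, cfg: CohortConfig) -> "TrueEffects":
        out = cls()
        for arm_name, prof in (("intervention", cfg.intervention),
                               ("control", cfg.control)):
            d = {
                "sb": prof.behavior_change[0],
                "lpa": prof.behavior_change[1],
                "mvpa": prof.behavior_change[2],
                "k6": prof.k6_change,
                "uwes": prof.uwes_change,
                "hpq": prof.hpq_change,
            }
            setattr(out, arm_name, d)
        return out

    def group_difference(self, outcome: str) -> float:
        return self.intervention[outcome] - self.control[outcome]


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class EpochBatch:
    """Work-window epoch streams for one visit, one row per worker-day."""

    met: np.ndarray            # (n_days, window) MET values
    steps: np.ndarray          # (n_days, window) step counts
    subject_idx: np.ndarray    # (n_days,) row index into the subject table
    day_of_subject: np.ndarray  # (n_days,) 0-based wear-day index


@dataclass
class Cohort:
    """Everything one simulated study produces."""

    subjects: pd.DataFrame
    epochs: dict                 # visit -> EpochBatch or None (tabular mode)
    latent_behavior: dict        # visit -> (n, 3) standardized targets
    effects: TrueEffects
    missing_report: pd.DataFrame
    mode: str


def generate_covariates(config: CohortConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Subject table with confounded arm assignment and exact arm sizes."""
    rng = rng or np.random.default_rng(config.seed)
    frames = []
    for arm in ("intervention", "control"):
        prof = _interp_profile(config, arm)
        n = prof.n
        frames.append(pd.DataFrame({
            "group": arm,
            "z": 1 if arm == "intervention" else 0,
            "age": rng.normal(prof.age_mean, prof.age_sd, n),
            "female": (rng.random(n) < prof.p_female).astype(int),
            "bmi": rng.normal(prof.bmi_mean, prof.bmi_sd, n),
            "manager": (rng.random(n) < prof.p_manager).astype(int),
        }))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "worker_id", [f"W{i:04d}" for i in range(len(out))])
    return out


def _zero_sum_devs(n: int, sd: np.ndarray, rng: np.random.Generator,
                   gamma_shape: float = 3.0) -> np.ndarray:
    """(n, 3) behavior deviations with the given SDs summing to zero per row.

    The MVPA deviation and the LPA residual are centered gammas (bounded
    below at -sd*sqrt(shape), right-skewed, as activity-time distributions
    are); LPA correlates with MVPA so the implied SB deviation -(LPA + MVPA)
    has the target SD.  Feasibility requires sd_sb <= sd_lpa + sd_mvpa.
    """
    sd_sb, sd_l, sd_m = sd
    rho = (sd_sb ** 2 - sd_l ** 2 - sd_m ** 2) / (2.0 * sd_l * sd_m)
    rho = float(np.clip(rho, -0.999, 0.999))

    def centered_gamma(scale, size):
        g = rng.gamma(gamma_shape, 1.0, size)
        return scale * (g - gamma_shape) / np.sqrt(gamma_shape)

    m = centered_gamma(sd_m, n)
    l = rho * (sd_l / sd_m) * m + centered_gamma(
        sd_l * np.sqrt(1.0 - rho ** 2), n)
    return np.column_stack([-(l + m), l, m])


def _behavior_targets(subjects: pd.DataFrame, config: CohortConfig,
                      rng: np.random.Generator) -> tuple[dict, np.ndarray]:
    """Latent standardized targets per visit plus per-subject nonwear fraction.

    Follow-up targets are baseline plus the arm's programmed change plus an
    independent zero-sum increment (random walk), so change scores carry no
    baseline dependence and the programmed change is the estimand in any
    covariate-weighted subpopulation.
    """
    n = len(subjects)
    targets = {v: np.zeros((n, 3)) for v in VISITS}
    nonwear = np.zeros(n)
    for arm in ("intervention", "control"):
        prof = _interp_profile(config, arm)
        sel = (subjects["group"] == arm).to_numpy()
        k = int(sel.sum())
        mean = np.asarray(prof.behavior_mean)
        dev_pre = _zero_sum_devs(k, np.asarray(prof.behavior_sd), rng)
        increment = _zero_sum_devs(k, np.asarray(prof.behavior_change_sd), rng)
        change = np.asarray(prof.behavior_change)
        targets["pre"][sel] = mean + dev_pre
        targets["post"][sel] = mean + change + dev_pre + increment
        f = rng.normal(prof.nonwear_frac_mean, prof.nonwear_frac_sd, k)
        nonwear[sel] = np.clip(f, 0.0, 0.20)
    # floors: keep every behavior non-negative (rare; zero-sum redistribution)
    for v in VISITS:
        t = np.maximum(targets[v], 0.05)
        targets[v] = t * (WORKDAY_MIN / t.sum(axis=1, keepdims=True))
    return targets, nonwear


def _wear_days(subjects: pd.DataFrame, config: CohortConfig,
               rng: np.random.Generator) -> np.ndarray:
    if config.wear_days_override is not None:
        return np.full(len(subjects), int(config.wear_days_override))
    days = np.zeros(len(subjects), dtype=int)
    for arm in ("intervention", "control"):
        prof = config.intervention if arm == "intervention" else config.control
        sel = (subjects["group"] == arm).to_numpy()
        draw = rng.normal(prof.wear_days_mean, prof.wear_days_sd, int(sel.sum()))
        days[sel] = np.maximum(1, np.round(draw)).astype(int)
    return days


def _epoch_batch(subjects: pd.DataFrame, targets: np.ndarray,
                 nonwear: np.ndarray, wear_days: np.ndarray,
                 config: CohortConfig, rng: np.random.Generator,
                 include: np.ndarray) -> EpochBatch:
    """Simulate all work-window epoch streams for one visit."""
    window = config.window_epochs()
    idx = np.flatnonzero(include)
    profiles = {arm: _interp_profile(config, arm)
                for arm in ("intervention", "control")}
    pis, dwells, rates = [], [], []
    for i in idx:
        prof = profiles[subjects["group"].iat[i]]
        wear_frac = 1.0 - nonwear[i]
        pi = np.concatenate(([nonwear[i]], wear_frac * targets[i] / WORKDAY_MIN))
        pis.append(pi / pi.sum())
        dwells.append(prof.dwell)
        rates.append(prof.step_rate)
    subject_idx = np.repeat(idx, wear_days[idx])
    chain_pi = np.repeat(np.array(pis), wear_days[idx], axis=0)
    P = _transition_matrices(np.array(pis), np.array(dwells))
    chain_P = np.repeat(P, wear_days[idx], axis=0)
    states = _simulate_chains(chain_P, chain_pi, window, rng)
    met = _met_for_states(states, rng)
    rate_per_day = np.repeat(np.array(rates), wear_days[idx])
    steps = rng.poisson(rate_per_day[:, None] * met * (states >= 2))
    day_of_subject = np.concatenate([np.arange(d) for d in wear_days[idx]]) \
        if idx.size else np.empty(0, dtype=int)
    return EpochBatch(met=met, steps=steps, subject_idx=subject_idx,
                      day_of_subject=day_of_subject)


def generate_epoch_stream(subject: pd.Series, config: CohortConfig,
                          visit: str, rng: np.random.Generator | None = None,
                          n_days: int | None = None) -> pd.DataFrame:
    """Epoch records for one subject-visit as a tidy frame.

    Stationary occupancy follows the subject's latent profile when the row
    carries ``target_sb/lpa/mvpa`` and ``nonwear_frac`` columns, else the
    arm-visit mean profile.
    """
    if visit not in VISITS:
        raise ValueError("visit must be 'pre' or 'post'")
    rng = rng or np.random.default_rng(config.seed)
    arm = subject["group"]
    prof = _interp_profile(config, arm)
    if {"target_sb", "target_lpa", "target_mvpa"} <= set(subject.index):
        target = np.array([subject["target_sb"], subject["target_lpa"],
                           subject["target_mvpa"]], dtype=float)
    else:
        target = np.asarray(prof.behavior_mean, dtype=float)
        if visit == "post":
            target = target + np.asarray(prof.behavior_change)
    f = float(subject.get("nonwear_frac", prof.nonwear_frac_mean))
    days = n_days if n_days is not None else max(1, round(prof.wear_days_mean))
    sub = pd.DataFrame({"group": [arm]})
    batch = _epoch_batch(
        sub, (target / target.sum() * WORKDAY_MIN)[None, :], np.array([f]),
        np.array([days]), config, rng, include=np.array([True]))
    return epochs_to_frame(batch, pd.DataFrame({"worker_id": [subject.get("worker_id", "W0000")]}),
                           visit, config)


def epochs_to_frame(batch: EpochBatch, subjects: pd.DataFrame, visit: str,
                    config: CohortConfig) -> pd.DataFrame:
    """Flatten an epoch batch to the external CSV layout
    (worker_id, date, time, met, steps)."""
    window = batch.met.shape[1] if batch.met.size else config.window_epochs()
    start_min = 60 * int(config.work_start.split(":")[0]) + int(config.work_start.split(":")[1])
    base_date = np.datetime64("2019-01-07") if visit == "pre" else np.datetime64("2020-02-03")
    n_days = batch.met.shape[0]
    times = [f"{(start_min + k) // 60:02d}:{(start_min + k) % 60:02d}:00"
             for k in range(window)]
    wid = subjects["worker_id"].to_numpy()[batch.subject_idx]
    return pd.DataFrame({
        "worker_id": np.repeat(wid, window),
        "date": np.repeat(base_date + batch.day_of_subject.astype("timedelta64[D]"), window),
        "time": np.tile(times, n_days),
        "met": batch.met.ravel(),
        "steps": batch.steps.ravel(),
    })


_SCALES = {
    "k6": dict(lo=0.0, hi=24.0, step=1.0),
    "uwes": dict(lo=0.0, hi=6.0, step=1.0 / UWES_DEFAULT_N_ITEMS),
    "hpq": dict(lo=0.0, hi=10.0, step=1.0),
}


def generate_outcomes(subjects: pd.DataFrame, config: CohortConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Add questionnaire item responses at both visits.

    Latent scores carry arm baselines and programmed follow-up changes;
    means are calibrated through the round/clamp observation map, and scores
    are decomposed into items whose standard scoring reproduces them.
    """
    rng = rng or np.random.default_rng(config.seed)
    out = subjects.copy()
    n = len(out)
    scores = {f"{s}_{v}": np.zeros(n) for s in _SCALES for v in VISITS}
    for arm in ("intervention", "control"):
        prof = _interp_profile(config, arm)
        sel = (out["group"] == arm).to_numpy()
        k = int(sel.sum())
        for scale, spec_ in _SCALES.items():
            base_mean, base_sd = getattr(prof, scale)
            change = getattr(prof, f"{scale}_change")
            change_sd = getattr(prof, f"{scale}_change_sd")
            post_sd = float(np.hypot(base_sd, change_sd))
            mu_pre = calibrate_latent_mean(base_mean, base_sd, **spec_)
            mu_post = calibrate_latent_mean(base_mean + change, post_sd, **spec_)
            dev = rng.normal(0.0, base_sd, k)
            increment = rng.normal(0.0, change_sd, k)
            scores[f"{scale}_pre"][sel] = observe_score(mu_pre + dev, **spec_)
            scores[f"{scale}_post"][sel] = observe_score(
                mu_post + dev + increment, **spec_)
    for v in VISITS:
        k6_items = np.stack([decompose_k6(t) for t in scores[f"k6_{v}"]])
        for j in range(K6_N_ITEMS):
            out[f"k6_item{j + 1}_{v}"] = k6_items[:, j].astype(float)
        uw_items = np.stack([decompose_uwes(s) for s in scores[f"uwes_{v}"]])
        for j in range(UWES_DEFAULT_N_ITEMS):
            out[f"uwes_item{j + 1}_{v}"] = uw_items[:, j].astype(float)
        out[f"hpq_{v}"] = scores[f"hpq_{v}"]
    return out


def generate_adherence(subjects: pd.DataFrame, config: CohortConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """4-level ordinal adherence recalls at three time points (intervention only)."""
    rng = rng or np.random.default_rng(config.seed)
    out = subjects.copy()
    interv = (out["group"] == "intervention").to_numpy()
    if interv.sum() == 0:
        raise ValueError("adherence requires a non-empty intervention arm")
    k = int(interv.sum())
    for tp in ADHERENCE_TIMES:
        probs = np.asarray(config.adherence_probs[tp], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("adherence probabilities must sum to 1")
        draws = rng.choice(len(ADHERENCE_LEVELS), size=k, p=probs)
        col = np.full(len(out), None, dtype=object)
        col[interv] = np.array(ADHERENCE_LEVELS, dtype=object)[draws]
        out[f"adherence_{tp}"] = col
    return out


def _mar_probs(driver: np.ndarray, rate: float, slope: float) -> np.ndarray:
    """Logistic MAR probabilities with intercept solved to hit ``rate``."""
    if rate <= 0.0:
        return np.zeros(driver.size)
    if rate >= 1.0:
        return np.ones(driver.size)
    z = (driver - np.nanmean(driver)) / max(np.nanstd(driver), 1e-9)
    z = np.nan_to_num(z)
    f = lambda a: np.mean(1.0 / (1.0 + np.exp(-(a + slope * z)))) - rate
    a = optimize.brentq(f, -30.0, 30.0)
    return 1.0 / (1.0 + np.exp(-(a + slope * z)))


def draw_missingness(subjects: pd.DataFrame, config: CohortConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Missingness indicator table (True = missing), MAR in observed age."""
    rng = rng or np.random.default_rng(config.seed)
    mc = config.missingness
    n = len(subjects)
    ind = pd.DataFrame(index=subjects.index)
    age = subjects["age"].to_numpy(dtype=float)
    arm_sel = {"intervention": (subjects["group"] == "intervention").to_numpy(),
               "control": (subjects["group"] == "control").to_numpy()}

    def _per_arm(rates, slope):
        out = np.zeros(n, dtype=bool)
        for j, arm in enumerate(("intervention", "control")):
            sel = arm_sel[arm]
            p = _mar_probs(age[sel], rates[j], slope)
            out[sel] = rng.random(int(sel.sum())) < p
        return out

    ind["accel"] = _per_arm(mc.accel, mc.mar_slope_accel)
    for var in ("age", "sex", "bmi", "manager"):
        ind[var] = _per_arm(getattr(mc, var), 0.0)
    for scale in ("k6", "uwes", "hpq"):
        for v in VISITS:
            ind[f"{scale}_{v}"] = _per_arm(getattr(mc, scale), mc.mar_slope_scale)
    for tp in ADHERENCE_TIMES:
        miss = np.zeros(n, dtype=bool)
        sel = arm_sel["intervention"]
        miss[sel] = rng.random(int(sel.sum())) < mc.adherence
        ind[f"adherence_{tp}"] = miss
    ind["attrition"] = _per_arm(mc.attrition, 0.0)
    return ind


def apply_missingness(subjects: pd.DataFrame, indicators: pd.DataFrame) -> pd.DataFrame:
    """Blank out item-level and covariate cells per the indicator table."""
    out = subjects.copy()
    col_map = {"age": ["age"], "sex": ["female"], "bmi": ["bmi"],
               "manager": ["manager"]}
    for scale in ("k6", "uwes", "hpq"):
        for v in VISITS:
            cols = [c for c in out.columns
                    if c.startswith(f"{scale}_item") and c.endswith(f"_{v}")]
            if scale == "hpq":
                cols = [f"hpq_{v}"]
            col_map[f"{scale}_{v}"] = cols
    for tp in ADHERENCE_TIMES:
        col_map[f"adherence_{tp}"] = [f"adherence_{tp}"]
    for var, cols in col_map.items():
        if var not in indicators:
            continue
        mask = indicators[var].to_numpy(dtype=bool)
        for c in cols:
            if c in out.columns:
                if out[c].dtype == object:
                    out.loc[mask, c] = None
                else:
                    out[c] = out[c].astype(float)
                    out.loc[mask, c] = np.nan
    attr = indicators["attrition"].to_numpy(dtype=bool)
    post_cols = [c for c in out.columns if c.endswith("_post")]
    for c in post_cols:
        out[c] = out[c].astype(float) if out[c].dtype != object else out[c]
        out.loc[attr, c] = np.nan if out[c].dtype != object else None
    return out


def simulate_cohort(config: CohortConfig, mode: str = "full",
                    seed: int | None = None) -> Cohort:
    """Generate a complete synthetic study.

    ``mode='full'`` emits epoch-level accelerometer streams for the device
    pipeline; ``mode='tabular'`` draws subject-level standardized metrics
    directly from the latent targets plus measurement noise (for fast
    Monte-Carlo work on the estimation stages; prolonged/bouted/step metrics
    are only available in full mode).
    """
    if mode not in ("full", "tabular"):
        raise ValueError("mode must be 'full' or 'tabular'")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    r_cov, r_lat, r_epoch, r_out, r_adh, r_miss, r_tab = \
        [np.random.default_rng(s) for s in ss.spawn(7)]

    subjects = generate_covariates(config, r_cov)
    targets, nonwear = _behavior_targets(subjects, config, r_lat)
    wear_days = _wear_days(subjects, config, r_lat)
    subjects["wear_days"] = wear_days
    subjects["nonwear_frac"] = nonwear

    subjects = generate_outcomes(subjects, config, r_out)
    subjects = generate_adherence(subjects, config, r_adh)
    indicators = draw_missingness(subjects, config, r_miss)
    effects = TrueEffects.from_config(config)

    epochs: dict = {"pre": None, "post": None}
    if mode == "full":
        include = ~indicators["accel"].to_numpy(dtype=bool)
        for v in VISITS:
            epochs[v] = _epoch_batch(subjects, targets[v], nonwear, wear_days,
                                     config, r_epoch, include)
    else:
        # day-level SDs of standardized metrics matching the epoch pipeline,
        # averaged over the subject's wear days
        day_sd = np.array([24.6, 24.3, 10.8])
        for v in VISITS:
            noise = _zero_sum_devs(len(subjects), day_sd, r_tab, gamma_shape=20.0)
            noise = noise / np.sqrt(np.maximum(wear_days, 1))[:, None]
            obs = targets[v] + noise
            drop = indicators["accel"].to_numpy(dtype=bool)
            for j, name in enumerate(("sb", "lpa", "mvpa")):
                col = obs[:, j].copy()
                col[drop] = np.nan
                subjects[f"{name}_{v}"] = col

    subjects = apply_missingness(subjects, indicators)
    report = pd.DataFrame({
        "variable": indicators.columns,
        "n_missing_intervention": [
            int(indicators.loc[subjects["group"] == "intervention", c].sum())
            for c in indicators.columns],
        "n_missing_control": [
            int(indicators.loc[subjects["group"] == "control", c].sum())
            for c in indicators.columns],
    })
    return Cohort(subjects=subjects, epochs=epochs, latent_behavior=targets,
                  effects=effects, missing_report=report, mode=mode)
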