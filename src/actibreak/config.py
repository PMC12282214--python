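"""Configuration objects for the active-break study pipeline.

Defaults are calibrated to the published baseline characteristics of the
two-arm cohort (172 intervention / 323 control office workers): demographics,
occupational movement-behavior profiles, questionnaire score distributions,
per-variable missing-data counts, and program-adherence shares.  All values
live here so that the synthetic cohort, the processing rules, and the
estimation stages share a single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: Length of the standard workday used for standardization, in minutes.
WORKDAY_MIN = 480

#: Outcomes the analysis stage knows how to estimate.  Accelerometer-derived
#: outcomes are standardized to the 8-hour workday; questionnaire outcomes are
#: on their native scales.
ACCEL_OUTCOMES = (
    "sb",
    "prolonged_sb_min",
    "prolonged_sb_count",
    "lpa",
    "mvpa",
    "bouted_pa_min",
    "bouted_pa_count",
    "steps",
)
QUESTIONNAIRE_OUTCOMES = ("k6", "uwes", "hpq")
ALL_OUTCOMES = ACCEL_OUTCOMES + QUESTIONNAIRE_OUTCOMES


def _zero_sum_adjust(changes: Sequence[float]) -> tuple[float, ...]:
    """Redistribute the imbalance of a behavior-change triple so it sums to 0.

    Standardized SB/LPA/MVPA minutes sum to 480 for every valid day, so true
    within-subject changes must sum to zero; published point estimates do not
    (they come from separately weighted models).  The equal redistribution
    keeps each programmed change as close as possible to its printed value.
    """
    resid = sum(changes) / len(changes)
    return tuple(c - resid for c in changes)


@dataclass
class ArmProfile:
    """Arm-conditional generative parameters (one per study arm)."""

    n: int
    # demographics
    age_mean: float
    age_sd: float
    p_female: float
    bmi_mean: float
    bmi_sd: float
    p_manager: float
    # occupational behavior, standardized min / 8 hrs (SB, LPA, MVPA)
    behavior_mean: tuple[float, float, float]
    behavior_sd: tuple[float, float, float]
    # fraction of the work window spent not wearing the device
    nonwear_frac_mean: float
    nonwear_frac_sd: float
    # accelerometer-wear protocol
    wear_days_mean: float
    wear_days_sd: float
    # Markov dwell times (min) for states (nonwear, SB, LPA, MVPA)
    dwell: tuple[float, float, float, float]
    # steps per MET-minute during activity epochs
    step_rate: float
    # questionnaire baselines: mean, sd
    k6: tuple[float, float]
    uwes: tuple[float, float]
    hpq: tuple[float, float]
    # true within-arm mean changes at follow-up; change-score noise is
    # independent of baseline (uniform effect), with the SDs below
    behavior_change: tuple[float, float, float]
    behavior_change_sd: tuple[float, float, float]
    k6_change: float
    uwes_change: float
    hpq_change: float
    k6_change_sd: float
    uwes_change_sd: float
    hpq_change_sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("arm size must be >= 2")
        if any(s < 0 for s in self.behavior_sd) or self.age_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        frac = sum(self.behavior_mean) / WORKDAY_MIN * (1.0 - self.nonwear_frac_mean)
        if not 0.0 < frac <= 1.0 + 1e-9:
            raise ValueError("behavior fractions must lie in (0, 1]")
        if not 0.0 <= self.nonwear_frac_mean < 1.0:
            raise ValueError("nonwear fraction must lie in [0, 1)")


def _norm480(v: Sequence[float]) -> tuple[float, float, float]:
    s = sum(v)
    return tuple(x * WORKDAY_MIN / s for x in v)  # type: ignore[return-value]


# Published baseline table, normalized so standardized minutes sum to 480.
_INT_BEHAVIOR = _norm480((308.1, 149.8, 23.1))
_CTL_BEHAVIOR = _norm480((341.4, 116.0, 23.7))

_INT_CHANGE = _zero_sum_adjust((-24.4, 12.6, 10.1))
_CTL_CHANGE = _zero_sum_adjust((1.4, -2.1, 0.5))


def default_intervention_profile() -> ArmProfile:
    return ArmProfile(
        n=172,
        age_mean=45.3, age_sd=11.6, p_female=0.924,
        bmi_mean=21.9, bmi_sd=3.3, p_manager=0.141,
        behavior_mean=_INT_BEHAVIOR,
        behavior_sd=(62.7, 56.7, 13.1),
        nonwear_frac_mean=(WORKDAY_MIN - 442.8) / WORKDAY_MIN,
        nonwear_frac_sd=30.8 / WORKDAY_MIN,
        wear_days_mean=4.7, wear_days_sd=0.5,
        dwell=(150.0, 10.0, 6.5, 5.0),
        step_rate=9.19,
        k6=(5.1, 5.2), uwes=(2.2, 0.9), hpq=(5.0, 1.3),
        behavior_change=_INT_CHANGE,
        behavior_change_sd=(48.0, 42.0, 13.0),
        k6_change=1.6, uwes_change=-0.1, hpq_change=0.2,
        k6_change_sd=4.3, uwes_change_sd=0.65, hpq_change_sd=1.8,
    )


def default_control_profile() -> ArmProfile:
    return ArmProfile(
        n=323,
        age_mean=51.6, age_sd=7.2, p_female=0.563,
        bmi_mean=23.3, bmi_sd=4.4, p_manager=0.282,
        behavior_mean=_CTL_BEHAVIOR,
        behavior_sd=(56.7, 53.0, 13.5),
        nonwear_frac_mean=(WORKDAY_MIN - 478.9) / WORKDAY_MIN,
        nonwear_frac_sd=6.1 / WORKDAY_MIN,
        wear_days_mean=12.2, wear_days_sd=4.5,
        dwell=(150.0, 13.7, 6.0, 5.0),
        step_rate=10.46,
        k6=(3.1, 4.0), uwes=(2.9, 1.5), hpq=(6.1, 1.6),
        behavior_change=_CTL_CHANGE,
        behavior_change_sd=(34.0, 31.0, 10.0),
        k6_change=0.1, uwes_change=0.1, hpq_change=0.4,
        k6_change_sd=4.2, uwes_change_sd=0.65, hpq_change_sd=1.6,
    )


@dataclass
class MissingnessConfig:
    """MAR missingness rates, calibrated to the published per-variable counts.

    Accelerometer missingness is a subject-level device dropout (both visits);
    subjects who fail the >=4-valid-day rule contribute additional metric-level
    missingness downstream, so the dropout rate is below the published total.
    ``mar_slope_*`` are log-odds per SD of age for the logistic MAR mechanism;
    intercepts are solved per arm so realized rates match the targets.
    """

    accel: tuple[float, float] = (0.010, 0.025)  # (intervention, control)
    age: tuple[float, float] = (6 / 172, 0.0)
    sex: tuple[float, float] = (2 / 172, 0.0)
    bmi: tuple[float, float] = (17 / 172, 0.0)
    manager: tuple[float, float] = (2 / 172, 0.0)
    k6: tuple[float, float] = (3 / 172, 2 / 323)
    uwes: tuple[float, float] = (3 / 172, 8 / 323)
    hpq: tuple[float, float] = (4 / 172, 1 / 323)
    adherence: float = 0.055  # per recall point, intervention arm only
    attrition: tuple[float, float] = (0.0, 0.0)
    mar_slope_accel: float = 0.5
    mar_slope_scale: float = 0.3

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name.startswith("mar_slope"):
                continue
            rates = value if isinstance(value, (tuple, list)) else (value,)
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError(f"missingness rate {name!r} outside [0, 1]")


#: Adherence response categories, worst to best.
ADHERENCE_LEVELS = ("almost_never", "sometimes", "mostly", "almost_always")
#: Recall points: program start, 6 months, 12 months.
ADHERENCE_TIMES = ("t0", "m6", "m12")

_DEF_ADHERENCE = {
    "t0": (0.057, 0.114, 0.208, 0.621),
    "m6": (0.062, 0.124, 0.228, 0.586),
    "m12": (0.050, 0.099, 0.182, 0.669),
}


@dataclass
class CohortConfig:
    """Everything the synthetic-cohort generator needs.

    ``confounding`` interpolates arm-conditional parameters between the pooled
    values (0: arms exchangeable) and the published arm-specific values (1:
    full confounding — older, more male, more managerial, more sedentary
    controls).  Follow-up deviations evolve as a random walk from baseline
    (change-score noise independent of baseline), so the programmed arm-mean
    changes are the estimand for any covariate-weighted population.
    """

    intervention: ArmProfile = field(default_factory=default_intervention_profile)
    control: ArmProfile = field(default_factory=default_control_profile)
    confounding: float = 1.0
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    adherence_probs: dict = field(default_factory=lambda: dict(_DEF_ADHERENCE))
    work_start: str = "09:00"
    work_end: str = "17:00"
    seed: int = 0
    # Reduced-volume switch used by the Monte-Carlo harness: fixes the wear-day
    # count per subject in both arms (None = arm-specific draw).
    wear_days_override: int | None = None

    def __post_init__(self) -> None:
        for tp, p in self.adherence_probs.items():
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"adherence probabilities at {tp!r} must sum to 1")
        if self.window_epochs() < 1:
            raise ValueError("work window must contain at least one 60-s epoch")

    def window_epochs(self) -> int:
        h0, m0 = map(int, self.work_start.split(":"))
        h1, m1 = map(int, self.work_end.split(":"))
        return (h1 * 60 + m1) - (h0 * 60 + m0)


@dataclass
class ImputationSpec:
    """Chained-equation / predictive-mean-matching settings."""

    m: int = 20
    n_iterations: int = 10
    k_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least m=2 imputations")
        if self.k_donors < 1:
            raise ValueError("k_donors must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class StudyConfig:
    """Top-level configuration for an end-to-end study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    outcomes: tuple[str, ...] = ALL_OUTCOMES
    complete_case: bool = True
    sandwich: str = "stacked"  # or "fixed" (weights held fixed)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("outcome list must be non-empty")
        unknown = set(self.outcomes) - set(ALL_OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}")
        if self.sandwich not in ("stacked", "fixed"):
            raise ValueError("sandwich must be 'stacked' or 'fixed'")


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def study_config_to_yaml(cfg: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def _tupled(d: dict, cls):
    kwargs = {}
    for name, f in cls.__dataclass_fields__.items():
        if name not in d:
            continue
        v = d[name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[name] = v
    return kwargs


def study_config_from_yaml(path) -> StudyConfig:
    """Load a StudyConfig from a YAML file; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.get("cohort", {})
    arms = {}
    for arm in ("intervention", "control"):
        base = (default_intervention_profile() if arm == "intervention"
                else default_control_profile())
        upd = cohort_raw.get(arm, {})
        merged = {**asdict(base), **_tupled(upd, ArmProfile)}
        arms[arm] = ArmProfile(**_tupled(merged, ArmProfile))
    miss = MissingnessConfig(**_tupled(cohort_raw.get("missingness", {}), MissingnessConfig))
    cohort_kwargs = _tupled(
        {k: v for k, v in cohort_raw.items()
         if k not in ("intervention", "control", "missingness")},
        CohortConfig,
    )
    if "adherence_probs" in cohort_kwargs:
        cohort_kwargs["adherence_probs"] = {
            k: tuple(v) for k, v in cohort_kwargs["adherence_probs"].items()
        }
    cohort = CohortConfig(intervention=arms["intervention"], control=arms["control"],
                          missingness=miss, **cohort_kwargs)
    imp = ImputationSpec(**_tupled(raw.get("imputation", {}), ImputationSpec))
    top = _tupled({k: v for k, v in raw.items() if k not in ("cohort", "imputation")},
                  StudyConfig)
    return StudyConfig(cohort=cohort, imputation=imp, **top)
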