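"""Scoring of the self-report instruments.

Three outcomes: the K6 psychological-distress scale (6 items scored 0-4,
summed to 0-24, higher = worse), work engagement on the Utrecht Work
Engagement Scale (items scored 0-6, reported as the item mean, higher =
better), and absolute presenteeism from the WHO Health and Work Performance
Questionnaire (a single 0-10 self-rating of job performance).  Any missing
item makes the scale score missing — no prorating; score-level missingness is
handled by multiple imputation downstream.

The adherence item asks, at follow-up, how often the respondent joined the
short active breaks at three recall points (program start, 6 and 12 months),
on a 4-level ordinal scale from "almost never" to "almost always".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import ADHERENCE_LEVELS, ADHERENCE_TIMES

K6_N_ITEMS = 6
K6_ITEM_RANGE = (0, 4)
UWES_DEFAULT_N_ITEMS = 9
UWES_ITEM_RANGE = (0, 6)
HPQ_RANGE = (0, 10)


def _check_items(items, lo, hi, name):
    arr = np.asarray(items, dtype=float)
    if np.isnan(arr).any():
        return None
    if np.any((arr < lo) | (arr > hi)):
        raise ValueError(f"{name} item outside [{lo}, {hi}]")
    return arr


def score_k6(items) -> float:
    """Sum of the six K6 items (0-24); NaN if any item is missing."""
    arr = np.asarray(items, dtype=float)
    if arr.size != K6_N_ITEMS:
        raise ValueError(f"K6 requires exactly {K6_N_ITEMS} items")
    arr = _check_items(arr, *K6_ITEM_RANGE, name="K6")
    return float("nan") if arr is None else float(arr.sum())


def score_uwes(items) -> float:
    """Mean of the work-engagement items (0-6); NaN if any item is missing."""
    arr = np.asarray(items, dtype=float)
    if arr.size == 0:
        raise ValueError("work-engagement scale requires at least one item")
    arr = _check_items(arr, *UWES_ITEM_RANGE, name="work engagement")
    return float("nan") if arr is None else float(arr.mean())


def score_presenteeism(rating) -> float:
    """Absolute presenteeism: the 0-10 rating itself; NaN when missing."""
    val = float(rating) if rating is not None else float("nan")
    if np.isnan(val):
        return val
    if not HPQ_RANGE[0] <= val <= HPQ_RANGE[1]:
        raise ValueError("presenteeism rating outside [0, 10]")
    return val


def score_subject_frame(subjects: pd.DataFrame,
                        uwes_items: int = UWES_DEFAULT_N_ITEMS) -> pd.DataFrame:
    """Score item-level columns into k6/uwes/hpq scores per visit.

    Expects columns ``k6_item{1..6}_{pre,post}``, ``uwes_item{1..n}_{pre,post}``
    and ``hpq_{pre,post}``; returns a copy with ``k6_pre`` ... ``hpq_post``.
    """
    out = subjects.copy()
    for visit in ("pre", "post"):
        k6_cols = [f"k6_item{i}_{visit}" for i in range(1, K6_N_ITEMS + 1)]
        uw_cols = [f"uwes_item{i}_{visit}" for i in range(1, uwes_items + 1)]
        out[f"k6_{visit}"] = [score_k6(r) for r in subjects[k6_cols].to_numpy()]
        out[f"uwes_{visit}"] = [score_uwes(r) for r in subjects[uw_cols].to_numpy()]
        out[f"hpq_{visit}"] = [score_presenteeism(v)
                               for v in subjects[f"hpq_{visit}"]]
    return out


def summarize_adherence(responses: pd.DataFrame) -> pd.DataFrame:
    """Complete-case adherence shares per category and recall point.

    ``responses`` holds one column per recall point (``adherence_t0``,
    ``adherence_m6``, ``adherence_m12``) with category labels or NaN.
    Respondents missing any recall point are excluded (the published summary
    uses only participants with no missing data at the three time points).
    Shares sum to 1 within each recall point.
    """
    cols = [f"adherence_{t}" for t in ADHERENCE_TIMES]
    complete = responses.dropna(subset=cols)
    if complete.empty:
        warnings.warn("no complete adherence cases; empty summary", stacklevel=2)
        return pd.DataFrame(index=pd.Index(ADHERENCE_LEVELS, name="response"),
                            columns=ADHERENCE_TIMES, dtype=float)
    out = {}
    for t, col in zip(ADHERENCE_TIMES, cols):
        counts = complete[col].value_counts()
        shares = np.array([counts.get(level, 0) for level in ADHERENCE_LEVELS],
                          dtype=float)
        out[t] = shares / shares.sum()
    summary = pd.DataFrame(out, index=pd.Index(ADHERENCE_LEVELS, name="response"))
    summary.attrs["n_complete"] = int(complete.shape[0])
    return summary
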