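"""Epoch-level accelerometer processing for occupational behavior metrics.

The device emits one MET value per 60-second epoch.  Processing follows the
study's device rules:

* intensity cut-points — SB at <=1.5 MET, LPA at 1.6-2.9 MET, MVPA at >=3.0
  MET, applied as half-open intervals so every MET value is classified;
* non-wear — any run of >=60 consecutive epochs at MET 0 (below the device's
  detection limit);
* working window — epochs whose start lies in [09:00, 17:00), i.e. 480 slots;
* valid day — wear time >= 75% of the working window;
* prolonged SB — unbroken SB runs of >=30 min;
* bouted PA — unbroken PA runs (LPA or MVPA, intensities may mix) lasting
  3-10 min, the band matching the program's break structure;
* standardization — observed minutes x 480 / wear minutes, per day;
* subject summary — mean over valid days, requiring >=4 valid days for
  inclusion (subjects below the threshold are left missing for imputation).

Zero-MET epochs in runs shorter than 60 min count as wear time; having no
printed intensity class above 0 they are tallied as SB (0 <= 1.5 MET), which
keeps SB + LPA + MVPA == wear time exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import WORKDAY_MIN

# epoch class codes
NONWEAR_CANDIDATE = 0
SB = 1
LPA = 2
MVPA = 3

#: Minimum run of zero-MET epochs that counts as non-wear.
NONWEAR_RUN_MIN = 60
#: Minimum length (min) of a prolonged sedentary bout.
PROLONGED_SB_MIN = 30
#: Bouted-PA band (min), inclusive.
BOUTED_PA_BAND = (3, 10)
#: Fraction of the working window that must be worn for a valid day.
VALID_DAY_FRACTION = 0.75
#: Valid days required for a subject's metrics to enter the analysis.
MIN_VALID_DAYS = 4

_CLASS_NAMES = {NONWEAR_CANDIDATE: "nonwear_candidate", SB: "SB", LPA: "LPA", MVPA: "MVPA"}


def classify_epoch(met):
    """Classify MET value(s) into SB / LPA / MVPA / non-wear candidate codes.

    SB is (0, 1.5], LPA is (1.5, 3.0), MVPA is [3.0, inf); MET 0 marks an
    epoch below the detection limit (a non-wear candidate).
    """
    met_arr = np.asarray(met, dtype=float)
    if np.any(met_arr < 0):
        raise ValueError("MET values must be >= 0")
    out = np.full(met_arr.shape, SB, dtype=np.int8)
    out[met_arr == 0.0] = NONWEAR_CANDIDATE
    out[met_arr > 1.5] = LPA
    out[met_arr >= 3.0] = MVPA
    return out if out.ndim else int(out)


def classify_epoch_label(met: float) -> str:
    """Single-epoch classification returning the class name."""
    return _CLASS_NAMES[int(classify_epoch(met))]


def _runs(flat: np.ndarray, row_id: np.ndarray):
    """Run-length encode ``flat``, breaking runs at row boundaries.

    Returns (start index, length, value, row) per run.
    """
    n = flat.size
    if n == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, e, e
    change = (flat[1:] != flat[:-1]) | (row_id[1:] != row_id[:-1])
    starts = np.concatenate(([0], np.flatnonzero(change) + 1))
    lengths = np.diff(np.concatenate((starts, [n])))
    return starts, lengths, flat[starts], row_id[starts]


def detect_nonwear(met: np.ndarray) -> np.ndarray:
    """Per-epoch wear flags for one contiguous worker-day stream.

    Every maximal run of >= 60 consecutive zero-MET epochs is non-wear; all
    other epochs — including zero runs of <= 59 min — are wear.
    """
    met = np.asarray(met, dtype=float)
    if met.ndim != 1:
        raise ValueError("expected a single day stream")
    zero = (met == 0.0).astype(np.int8)
    starts, lengths, values, _ = _runs(zero, np.zeros(met.size, dtype=np.int64))
    wear_per_run = ~((values == 1) & (lengths >= NONWEAR_RUN_MIN))
    return np.repeat(wear_per_run, lengths)


def is_valid_day(wear_min: float, window_min: int = WORKDAY_MIN) -> bool:
    """A day is valid when the device was worn >= 75% of the working window."""
    return bool(wear_min >= VALID_DAY_FRACTION * window_min)


def standardize(raw, wear_min):
    """Standardize an observed quantity to the 8-hour (480-min) workday.

    ``raw x 480 / wear_min``; undefined (NaN) when nothing was worn.
    """
    raw = np.asarray(raw, dtype=float)
    wear = np.asarray(wear_min, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(wear > 0, raw * WORKDAY_MIN / wear, np.nan)
    return out if out.ndim else float(out)


def _superstate(eff: np.ndarray) -> np.ndarray:
    # 0 = non-wear, 1 = SB, 2 = PA (LPA or MVPA merged)
    out = np.ones(eff.shape, dtype=np.int8)
    out[eff == NONWEAR_CANDIDATE] = 0
    out[eff >= LPA] = 2
    return out


def compute_bouts(classes: np.ndarray, long_pa_runs: str = "exclude"):
    """Bout metrics for one day of wear-resolved epoch classes.

    ``classes`` uses the module's codes with NONWEAR_CANDIDATE marking
    detected non-wear (which breaks any run).  Prolonged SB counts maximal SB
    runs >= 30 min; bouted PA counts maximal PA runs of 3-10 min, where a PA
    run may mix LPA and MVPA epochs.  Runs longer than 10 min are excluded
    from bouted PA by default, or credited 10 min each with
    ``long_pa_runs='truncate'``.

    Returns (prolonged_sb_min, prolonged_sb_count, bouted_pa_min,
    bouted_pa_count).
    """
    classes = np.asarray(classes)
    if np.any((classes < NONWEAR_CANDIDATE) | (classes > MVPA)):
        raise ValueError("unclassified epoch in bout computation")
    sup = _superstate(classes)
    _, lengths, values, _ = _runs(sup, np.zeros(sup.size, dtype=np.int64))
    sb_runs = lengths[(values == 1) & (lengths >= PROLONGED_SB_MIN)]
    lo, hi = BOUTED_PA_BAND
    pa_lengths = lengths[values == 2]
    in_band = pa_lengths[(pa_lengths >= lo) & (pa_lengths <= hi)]
    if long_pa_runs == "truncate":
        n_long = int(np.sum(pa_lengths > hi))
        pa_min = int(in_band.sum()) + n_long * hi
        pa_count = in_band.size + n_long
    elif long_pa_runs == "exclude":
        pa_min = int(in_band.sum())
        pa_count = in_band.size
    else:
        raise ValueError("long_pa_runs must be 'exclude' or 'truncate'")
    return int(sb_runs.sum()), int(sb_runs.size), pa_min, int(pa_count)


_RAW_COLS = ["sb_min", "lpa_min", "mvpa_min", "prolonged_sb_min",
             "prolonged_sb_count", "bouted_pa_min", "bouted_pa_count", "steps"]
#: standardized column name per analysis outcome
STD_COLS = {"sb": "std_sb", "lpa": "std_lpa", "mvpa": "std_mvpa",
            "prolonged_sb_min": "std_prolonged_sb_min",
            "prolonged_sb_count": "std_prolonged_sb_count",
            "bouted_pa_min": "std_bouted_pa_min",
            "bouted_pa_count": "std_bouted_pa_count",
            "steps": "std_steps"}


def process_days(met: np.ndarray, steps: np.ndarray,
                 long_pa_runs: str = "exclude") -> pd.DataFrame:
    """Daily metrics for a batch of day streams (rows = worker-days).

    The fully vectorized path: classification, non-wear detection, bout
    extraction and standardization in one run-length pass over all days.
    """
    met = np.atleast_2d(np.asarray(met, dtype=float))
    steps = np.atleast_2d(np.asarray(steps, dtype=float))
    n_days, window = met.shape
    flat = met.ravel()
    cls = classify_epoch(flat)
    row_id = np.repeat(np.arange(n_days, dtype=np.int64), window)

    # non-wear: zero runs >= 60 within each day
    zero = (cls == NONWEAR_CANDIDATE).astype(np.int8)
    starts, lengths, values, rows = _runs(zero, row_id)
    wear = np.repeat(~((values == 1) & (lengths >= NONWEAR_RUN_MIN)), lengths)

    # effective class: non-wear / SB (wear zeros tally as SB) / LPA / MVPA
    eff = np.where(wear, np.where(cls == NONWEAR_CANDIDATE, SB, cls),
                   NONWEAR_CANDIDATE).astype(np.int8)

    wear_min = np.bincount(row_id, weights=wear, minlength=n_days)
    sb_min = np.bincount(row_id, weights=(eff == SB), minlength=n_days)
    lpa_min = np.bincount(row_id, weights=(eff == LPA), minlength=n_days)
    mvpa_min = np.bincount(row_id, weights=(eff == MVPA), minlength=n_days)
    steps_day = np.bincount(row_id, weights=steps.ravel() * wear, minlength=n_days)

    sup = _superstate(eff)
    _, rl, rv, rr = _runs(sup, row_id)
    long_sb = (rv == 1) & (rl >= PROLONGED_SB_MIN)
    prolonged_min = np.bincount(rr[long_sb], weights=rl[long_sb], minlength=n_days)
    prolonged_cnt = np.bincount(rr[long_sb], minlength=n_days).astype(float)
    lo, hi = BOUTED_PA_BAND
    pa_band = (rv == 2) & (rl >= lo) & (rl <= hi)
    bouted_min = np.bincount(rr[pa_band], weights=rl[pa_band], minlength=n_days)
    bouted_cnt = np.bincount(rr[pa_band], minlength=n_days).astype(float)
    if long_pa_runs == "truncate":
        pa_long = (rv == 2) & (rl > hi)
        bouted_min = bouted_min + np.bincount(rr[pa_long], minlength=n_days) * hi
        bouted_cnt = bouted_cnt + np.bincount(rr[pa_long], minlength=n_days)
    elif long_pa_runs != "exclude":
        raise ValueError("long_pa_runs must be 'exclude' or 'truncate'")

    out = pd.DataFrame({
        "wear_min": wear_min, "sb_min": sb_min, "lpa_min": lpa_min,
        "mvpa_min": mvpa_min, "prolonged_sb_min": prolonged_min,
        "prolonged_sb_count": prolonged_cnt, "bouted_pa_min": bouted_min,
        "bouted_pa_count": bouted_cnt, "steps": steps_day,
    })
    out["valid"] = out["wear_min"] >= VALID_DAY_FRACTION * window
    raw_for = {"sb": "sb_min", "lpa": "lpa_min", "mvpa": "mvpa_min",
               "prolonged_sb_min": "prolonged_sb_min",
               "prolonged_sb_count": "prolonged_sb_count",
               "bouted_pa_min": "bouted_pa_min",
               "bouted_pa_count": "bouted_pa_count", "steps": "steps"}
    for key, std_col in STD_COLS.items():
        out[std_col] = standardize(out[raw_for[key]].to_numpy(), wear_min)
    return out


def process_day(met: np.ndarray, steps: np.ndarray | None = None,
                long_pa_runs: str = "exclude") -> dict:
    """DailyMetrics for a single contiguous day stream, as a dict."""
    met = np.asarray(met, dtype=float)
    if steps is None:
        steps = np.zeros_like(met)
    return process_days(met[None, :], np.asarray(steps, dtype=float)[None, :],
                        long_pa_runs=long_pa_runs).iloc[0].to_dict()


def extract_working_window(epochs: pd.DataFrame, start: str = "09:00",
                           end: str = "17:00") -> pd.DataFrame:
    """Keep epochs whose start time lies in the half-open window [start, end)."""
    t0 = _minute_of_day(start)
    t1 = _minute_of_day(end)
    if t1 <= t0:
        raise ValueError("work window must have positive length")
    minutes = epochs["time"].map(_minute_of_day)
    return epochs.loc[(minutes >= t0) & (minutes < t1)]


def _minute_of_day(hhmm: str) -> int:
    parts = str(hhmm).split(":")
    return int(parts[0]) * 60 + int(parts[1])


def process_epoch_frame(epochs: pd.DataFrame, start: str = "09:00",
                        end: str = "17:00",
                        long_pa_runs: str = "exclude") -> pd.DataFrame:
    """Daily metrics from a tidy epoch table.

    ``epochs`` has columns worker_id, date, time, met, steps — one row per
    60-second epoch.  Streams must be contiguous at 60-s spacing inside the
    working window; gaps raise an error.
    """
    window = extract_working_window(epochs, start, end)
    if window.empty:
        return pd.DataFrame(columns=["worker_id", "date"])
    window = window.sort_values(["worker_id", "date", "time"])
    width = _minute_of_day(end) - _minute_of_day(start)
    counts = window.groupby(["worker_id", "date"], sort=False).size()
    if (counts != width).any():
        bad = counts[counts != width].index[0]
        raise ValueError(f"gap in epoch sequence for worker-day {bad}")
    met = window["met"].to_numpy(dtype=float).reshape(-1, width)
    steps = window["steps"].to_numpy(dtype=float).reshape(-1, width)
    daily = process_days(met, steps, long_pa_runs=long_pa_runs)
    keys = counts.index.to_frame(index=False)
    return pd.concat([keys.reset_index(drop=True), daily], axis=1)


def summarize_subject(daily: pd.DataFrame) -> dict:
    """Per-subject behavior summary: mean standardized metrics on valid days.

    Subjects with fewer than 4 valid days keep their row but all metrics are
    missing (NaN) — they are imputed downstream, mirroring the study's
    handling of insufficient wear.
    """
    valid = daily.loc[daily["valid"]]
    n_valid = int(valid.shape[0])
    meets = n_valid >= MIN_VALID_DAYS
    out = {"n_valid_days": n_valid, "meets_inclusion": meets}
    for key, std_col in STD_COLS.items():
        out[key] = float(valid[std_col].mean()) if meets else np.nan
    out["weartime"] = float(valid["wear_min"].mean()) if meets else np.nan
    return out


def summarize_subjects(daily: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`summarize_subject` per worker-id."""
    std_cols = list(STD_COLS.values())
    valid = daily.loc[daily["valid"], ["worker_id", "wear_min", *std_cols]]
    n_valid = valid.groupby("worker_id", sort=False).size()
    means = valid.groupby("worker_id", sort=False)[["wear_min", *std_cols]].mean()
    out = pd.DataFrame({"worker_id": daily["worker_id"].unique()})
    out["n_valid_days"] = out["worker_id"].map(n_valid).fillna(0).astype(int)
    out["meets_inclusion"] = out["n_valid_days"] >= MIN_VALID_DAYS
    out["weartime"] = out["worker_id"].map(means["wear_min"])
    for key, std_col in STD_COLS.items():
        out[key] = out["worker_id"].map(means[std_col])
    mask = ~out["meets_inclusion"]
    out.loc[mask, ["weartime", *STD_COLS.keys()]] = np.nan
    return out
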