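"""Behavioural measures for T-maze spontaneous alternation.

Trials comprise a sample run and a choice run; a trial is successful
(alternated) when the two runs end in different goal arms.  Trial
latency is the time from start-door raise to the final decision-point
crossing; trials with a latency above 120 s on either run are excluded.
Running speed (25 Hz) is smoothed with a 400-ms boxcar and immobility
is strictly ``speed < 2 cm/s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LATENCY_LIMIT_S", "IMMOBILITY_THRESHOLD", "BOXCAR_SAMPLES",
    "MovementSummary", "trial_latency", "score_trials", "alternation_rate",
    "smooth_speed", "immobility_mask", "movement_summary",
]

LATENCY_LIMIT_S = 120.0
IMMOBILITY_THRESHOLD = 2.0   # cm/s, strict "lower than"
BOXCAR_SAMPLES = 10          # 400 ms at 25 Hz


@dataclass
class MovementSummary:
    mean_speed: float                    # cm/s, whole session
    immobility_proportion: float         # whole session, [0, 1]
    predecision_immobility: float        # mean over trials, [0, 1]


def trial_latency(door_raise_s: float, decision_cross_s: float) -> float:
    """Seconds from door raise to the decision-point crossing."""
    if decision_cross_s <= door_raise_s:
        raise ValueError(
            f"decision crossing ({decision_cross_s}) precedes door raise "
            f"({door_raise_s})")
    return float(decision_cross_s - door_raise_s)


def score_trials(events: pd.DataFrame) -> pd.DataFrame:
    """Per-trial outcomes from the run-level event table.

    Returns one row per trial with the arms chosen on each run, the
    alternation flag, both latencies, and the exclusion flag (latency
    above 120 s on either run).
    """
    rows = []
    for trial_id, g in events.groupby("trial_id", sort=True):
        runs = {r["run"]: r for _, r in g.iterrows()}
        if "sample" not in runs or "choice" not in runs:
            raise ValueError(f"trial {trial_id} lacks a sample or choice run")
        lat = {run: trial_latency(runs[run]["door_raise_s"],
                                  runs[run]["decision_cross_s"])
               for run in ("sample", "choice")}
        excluded = lat["sample"] > LATENCY_LIMIT_S or lat["choice"] > LATENCY_LIMIT_S
        rows.append({
            "trial_id": trial_id,
            "sample_arm": runs["sample"]["arm"],
            "choice_arm": runs["choice"]["arm"],
            "alternated": runs["sample"]["arm"] != runs["choice"]["arm"],
            "latency_sample": lat["sample"],
            "latency_choice": lat["choice"],
            "excluded": excluded,
            "exclusion_reason": "latency exceeded 120 s" if excluded else "",
        })
    return pd.DataFrame(rows)


def alternation_rate(outcomes: pd.DataFrame) -> float:
    """Proportion of successful (alternated) trials among usable ones."""
    usable = outcomes[~outcomes["excluded"]]
    if len(usable) == 0:
        raise ValueError("no non-excluded trials; alternation rate undefined")
    return float(usable["alternated"].mean())


def smooth_speed(speed: np.ndarray, window: int = BOXCAR_SAMPLES) -> np.ndarray:
    """Centered boxcar moving average; edges use a shrinking window."""
    speed = np.asarray(speed, float)
    if speed.size == 0:
        raise ValueError("empty speed trace")
    if speed.size < window:
        raise ValueError(f"need at least {window} samples")
    return (pd.Series(speed)
            .rolling(window=window, center=True, min_periods=1)
            .mean().to_numpy())


def immobility_mask(smoothed_speed: np.ndarray,
                    threshold: float = IMMOBILITY_THRESHOLD):
    """Boolean immobility mask (strictly below threshold) + proportion."""
    speed = np.asarray(smoothed_speed, float)
    mask = speed < threshold
    return mask, float(mask.mean()) if mask.size else 0.0


def movement_summary(tracking: pd.DataFrame, events: pd.DataFrame,
                     window: int = BOXCAR_SAMPLES,
                     threshold: float = IMMOBILITY_THRESHOLD) -> MovementSummary:
    """Session-level movement statistics from the tracking trace.

    Pre-decision immobility is the mean, over runs, of the immobile
    fraction of each ``[door raise, decision cross)`` interval.
    """
    sm = smooth_speed(tracking["speed_cm_s"].to_numpy(), window)
    t = tracking["time_s"].to_numpy()
    mask, prop = immobility_mask(sm, threshold)
    per_run = []
    for _, ev in events.iterrows():
        sel = (t >= ev["door_raise_s"]) & (t < ev["decision_cross_s"])
        if sel.any():
            per_run.append(float(mask[sel].mean()))
    return MovementSummary(
        mean_speed=float(sm.mean()),
        immobility_proportion=prop,
        predecision_immobility=float(np.mean(per_run)) if per_run else np.nan,
    )
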