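"""Participant-level aggregation, step-defined levels and BMI categories.

Day profiles are averaged with unweighted arithmetic means over a selected
day set: valid days (default; days with >= 10 h wear) or all worn days
(any wear at all).  Guideline achievement is evaluated on valid days only.

The step-defined activity scale classifies mean censored steps/day into six
bands, from basal (< 2,500) to highly active (>= 12,500 steps/day).  BMI
categories use the conventional half-open bands with normal = [18.5, 25).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

from .bouts import BoutParams, meets_guideline
from .day_metrics import DayProfile

STEP_LEVELS = (
    "basal",
    "limited",
    "low_active",
    "somewhat_active",
    "active",
    "highly_active",
)
DEFAULT_STEP_BOUNDS = (2500.0, 5000.0, 7500.0, 10000.0, 12500.0)

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
BMI_BOUNDS = (18.5, 25.0, 30.0)


class ExclusionError(ValueError):
    """A participant cannot be profiled; carries a reason code."""

    def __init__(self, participant_id: str, reason: str):
        super().__init__(f"participant {participant_id!r} excluded: {reason}")
        self.participant_id = participant_id
        self.reason = reason


@dataclass(frozen=True)
class ParticipantProfile:
    """Day-averaged indicators plus categorical classifications."""

    participant_id: str
    n_days_worn: int
    n_valid_days: int
    mean_wear_minutes: float
    mean_nonwear_minutes: float
    mean_activity_counts: float
    mean_steps_uncensored: float
    mean_steps_censored: float
    mean_minutes_sedentary: float
    mean_minutes_low: float
    mean_minutes_light: float
    mean_minutes_moderate: float
    mean_minutes_vigorous: float
    mean_breaks: float
    mean_mvpa_bout_minutes: float
    mean_counts_per_min: float
    mean_steps_uncensored_per_min: float
    mean_steps_censored_per_min: float
    guideline_met: bool
    step_level: str
    bmi_category: str | None = None


def classify_step_level(
    mean_censored_steps_per_day: float,
    bounds: Sequence[float] = DEFAULT_STEP_BOUNDS,
) -> str:
    """Map mean censored steps/day onto the six-level step-defined scale."""
    if mean_censored_steps_per_day < 0:
        raise ValueError("steps/day must be non-negative")
    if len(bounds) != len(STEP_LEVELS) - 1 or list(bounds) != sorted(bounds):
        raise ValueError("bounds must be 5 ascending cut values")
    return STEP_LEVELS[bisect_right(bounds, mean_censored_steps_per_day)]


def bmi_category(bmi: float) -> str | None:
    """BMI (kg/m^2) category; None signals a missing BMI."""
    if bmi is None or (isinstance(bmi, float) and math.isnan(bmi)):
        return None
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    return BMI_CATEGORIES[bisect_right(BMI_BOUNDS, bmi)]


def aggregate_participant(
    days: Sequence[DayProfile],
    averaging: str = "valid_days",
    *,
    bout_params: BoutParams = BoutParams(),
    step_bounds: Sequence[float] = DEFAULT_STEP_BOUNDS,
    bmi: float | None = None,
) -> ParticipantProfile:
    """Average one participant's day profiles into a ParticipantProfile.

    Raises ExclusionError (reason ``no_valid_day``) when no day reaches the
    wear-time validity threshold, matching the study's exclusion cascade.
    """
    if averaging not in ("valid_days", "worn_days"):
        raise ValueError("averaging must be 'valid_days' or 'worn_days'")
    if not days:
        raise ValueError("no day profiles supplied")
    pid = days[0].participant_id
    if any(d.participant_id != pid for d in days):
        raise ValueError("day profiles from multiple participants")
    worn = [d for d in days if d.wear_minutes > 0]
    valid = [d for d in days if d.valid]
    if not valid:
        raise ExclusionError(pid, "no_valid_day")
    selected = valid if averaging == "valid_days" else worn

    def mean(attr: str) -> float:
        return sum(getattr(d, attr) for d in selected) / len(selected)

    mean_steps_censored = mean("steps_censored")
    met = meets_guideline(
        [(d.day_index, d.mvpa_bout_minutes, d.valid) for d in days], bout_params
    )
    return ParticipantProfile(
        participant_id=pid,
        n_days_worn=len(worn),
        n_valid_days=len(valid),
        mean_wear_minutes=mean("wear_minutes"),
        mean_nonwear_minutes=mean("nonwear_minutes"),
        mean_activity_counts=mean("activity_counts_total"),
        mean_steps_uncensored=mean("steps_uncensored"),
        mean_steps_censored=mean_steps_censored,
        mean_minutes_sedentary=mean("minutes_sedentary"),
        mean_minutes_low=mean("minutes_low"),
        mean_minutes_light=mean("minutes_light"),
        mean_minutes_moderate=mean("minutes_moderate"),
        mean_minutes_vigorous=mean("minutes_vigorous"),
        mean_breaks=mean("breaks"),
        mean_mvpa_bout_minutes=mean("mvpa_bout_minutes"),
        mean_counts_per_min=_mean_rate(selected, "activity_counts_total"),
        mean_steps_uncensored_per_min=_mean_rate(selected, "steps_uncensored"),
        mean_steps_censored_per_min=_mean_rate(selected, "steps_censored"),
        guideline_met=bool(met),
        step_level=classify_step_level(mean_steps_censored, step_bounds),
        bmi_category=bmi_category(bmi) if bmi is not None else None,
    )


def _mean_rate(selected: Sequence[DayProfile], attr: str) -> float:
    # per-day rate (volume / worn minutes) averaged over the day set;
    # selected days all have wear > 0 by construction
    return sum(getattr(d, attr) / d.wear_minutes for d in selected) / len(selected)
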