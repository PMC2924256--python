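"""Per-day indicators: intensity time, volumes, censored steps, breaks.

Intensity bands are half-open with inclusive lower bounds, following the
integer count ranges of the NHANES cut-point scheme: sedentary [0, 100),
low [100, 500), light [500, 2020), moderate [2020, 6000) and vigorous
[6000, inf) counts/min.  Non-wear takes precedence over intensity: a zero
minute inside a qualifying zero run is non-wear, never sedentary.

Censored steps zero out steps from minutes below 500 counts/min (low and
sedentary intensities), aligning accelerometer step totals with
research-grade pedometer scales; activity-count totals are never censored.

A break in sedentary time is an adjacent pair of worn minutes where counts
rise from below the sedentary bound (< 100) to at or above it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .bouts import BoutParams, bout_minutes, find_bouts
from .epochs import MINUTES_PER_DAY, EpochDay
from .wear import WearMask, detect_nonwear, is_valid_day, wear_minutes


class Intensity(enum.IntEnum):
    NONWEAR = 0
    SEDENTARY = 1
    LOW = 2
    LIGHT = 3
    MODERATE = 4
    VIGOROUS = 5


INTENSITY_NAMES = tuple(i.name.lower() for i in Intensity)


@dataclass(frozen=True)
class CutPointScheme:
    """Exclusive upper bounds of the count bands (counts/min)."""

    sedentary_upper: int = 100
    low_upper: int = 500
    light_upper: int = 2020
    moderate_upper: int = 6000

    def __post_init__(self) -> None:
        if not (0 < self.sedentary_upper < self.low_upper < self.light_upper < self.moderate_upper):
            raise ValueError("cut points must satisfy 0 < sedentary < low < light < moderate")

    @property
    def bins(self) -> np.ndarray:
        return np.array(
            [self.sedentary_upper, self.low_upper, self.light_upper, self.moderate_upper]
        )


@dataclass(frozen=True)
class DayProfile:
    """All per-day indicators for one participant-day."""

    participant_id: str
    day_index: int
    wear_minutes: int
    nonwear_minutes: int
    activity_counts_total: int
    steps_uncensored: int
    steps_censored: int
    minutes_sedentary: int
    minutes_low: int
    minutes_light: int
    minutes_moderate: int
    minutes_vigorous: int
    breaks: int
    mvpa_bout_minutes: int
    valid: bool


@dataclass(frozen=True)
class RateIndicators:
    """Per-worn-minute rates; NaN marks the undefined zero-wear case."""

    counts_per_min: float
    steps_uncensored_per_min: float
    steps_censored_per_min: float


def classify_intensity(
    day: EpochDay, mask: WearMask, scheme: CutPointScheme = CutPointScheme()
) -> np.ndarray:
    """Per-minute Intensity codes; non-wear wins regardless of counts."""
    labels = np.digitize(day.counts, scheme.bins) + 1  # 1..5
    labels[~mask.worn] = Intensity.NONWEAR
    return labels.astype(np.int8)


def time_in_intensity(labels: np.ndarray) -> dict[str, int]:
    """Minutes per intensity class; the six classes always sum to 1,440."""
    if labels.shape != (MINUTES_PER_DAY,):
        raise ValueError("expected 1440 per-minute labels")
    tally = np.bincount(labels, minlength=len(Intensity))
    return {name: int(tally[i]) for i, name in enumerate(INTENSITY_NAMES)}


def daily_volume(day: EpochDay, censor_below: int = 500) -> tuple[int, int, int]:
    """(activity counts total, uncensored steps, censored steps) for the day.

    Censoring drops steps from minutes with counts < ``censor_below``; the
    count total itself is never censored.
    """
    keep = day.counts >= censor_below
    return (
        int(day.counts.sum()),
        int(day.steps.sum()),
        int(day.steps[keep].sum()),
    )


def rate_indicators(profile: DayProfile) -> RateIndicators:
    """Volumes divided by worn minutes; undefined (NaN) when wear is zero."""
    if profile.wear_minutes == 0:
        return RateIndicators(math.nan, math.nan, math.nan)
    w = profile.wear_minutes
    return RateIndicators(
        profile.activity_counts_total / w,
        profile.steps_uncensored / w,
        profile.steps_censored / w,
    )


def count_sedentary_breaks(labels: np.ndarray) -> int:
    """Breaks in sedentary time from per-minute intensity labels.

    Counts adjacent minute pairs (t, t+1) where t is sedentary wear and
    t+1 is wear at or above the sedentary bound; pairs touching non-wear
    are not counted.
    """
    a, b = labels[:-1], labels[1:]
    return int(((a == Intensity.SEDENTARY) & (b >= Intensity.LOW)).sum())


def profile_day(
    day: EpochDay,
    scheme: CutPointScheme = CutPointScheme(),
    *,
    min_zero_run: int = 60,
    min_wear: int = 600,
    censor_below: int = 500,
    bout_params: BoutParams = BoutParams(),
    mask: WearMask | None = None,
) -> DayProfile:
    """Compute the full per-day indicator profile for one participant-day."""
    if mask is None:
        mask = detect_nonwear(day, min_zero_run)
    labels = classify_intensity(day, mask, scheme)
    times = time_in_intensity(labels)
    counts_total, steps_unc, steps_cen = daily_volume(day, censor_below)
    wm = wear_minutes(mask)
    return DayProfile(
        participant_id=day.participant_id,
        day_index=day.day_index,
        wear_minutes=wm,
        nonwear_minutes=MINUTES_PER_DAY - wm,
        activity_counts_total=counts_total,
        steps_uncensored=steps_unc,
        steps_censored=steps_cen,
        minutes_sedentary=times["sedentary"],
        minutes_low=times["low"],
        minutes_light=times["light"],
        minutes_moderate=times["moderate"],
        minutes_vigorous=times["vigorous"],
        breaks=count_sedentary_breaks(labels),
        mvpa_bout_minutes=bout_minutes(find_bouts(day, mask, bout_params)),
        valid=is_valid_day(mask, min_wear),
    )
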