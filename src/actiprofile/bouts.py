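"""Modified 10-minute MVPA bout detection and guideline evaluation.

A modified bout is an episode of at least ``min_above_minutes`` minutes at
or above the moderate-intensity count threshold (2,020 counts/min under the
NHANES cut points), tolerating internal below-threshold interruptions of at
most ``max_interruption_run`` consecutive minutes; a below-threshold run of
``termination_run`` minutes ends the episode.  With the defaults (2-minute
allowance, 3-minute termination) the two closure rules coincide: the first
below-threshold run that exceeds the allowance terminates the bout.  Only
above-threshold minutes are credited toward bout minutes.

The public-health guideline is accumulating ``daily_target`` (30) bout
minutes on at least ``days_target`` (5) of ``window_days`` (7) days; it is
evaluated deterministically on the observed valid days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .epochs import EpochDay
from .wear import WearMask


@dataclass(frozen=True)
class BoutParams:
    threshold: int = 2020  # counts/min, inclusive lower bound of "above"
    min_above_minutes: int = 10
    max_interruption_run: int = 2
    termination_run: int = 3
    daily_target: int = 30
    days_target: int = 5
    window_days: int = 7

    def __post_init__(self) -> None:
        if self.max_interruption_run >= self.termination_run:
            raise ValueError("max_interruption_run must be < termination_run")
        if self.min_above_minutes < 1:
            raise ValueError("min_above_minutes must be >= 1")
        if self.daily_target < self.min_above_minutes:
            raise ValueError("daily_target must be >= min_above_minutes")


@dataclass(frozen=True)
class Bout:
    """Half-open minute interval starting and ending on above-threshold minutes."""

    start_minute: int
    end_minute: int
    above_minutes: int


def find_bouts(day: EpochDay, mask: WearMask, params: BoutParams = BoutParams()) -> list[Bout]:
    """Detect modified bouts in one day, scanning wear minutes left to right.

    A candidate opens at a worn minute with counts >= threshold, continues
    through above-threshold minutes and below-threshold runs of length <=
    ``max_interruption_run``, and closes when a below-threshold run exceeds
    the allowance, a non-wear minute occurs, or the day ends.  Trailing
    below-threshold minutes are trimmed, and the candidate is emitted iff it
    accumulated at least ``min_above_minutes`` above-threshold minutes.
    Bouts are disjoint and ordered.
    """
    above = mask.worn & (day.counts >= params.threshold)
    # run-length encode the day into (above?, worn?, start, end) segments
    segs: list[tuple[bool, bool, int, int]] = []
    state = np.where(~mask.worn, 2, above.astype(np.int8))  # 0 below, 1 above, 2 nonwear
    change = np.nonzero(np.diff(state))[0] + 1
    bounds = [0, *change.tolist(), len(state)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        segs.append((state[s] == 1, state[s] != 2, s, e))

    bouts: list[Bout] = []
    start = last_above_end = -1
    above_ct = 0

    def close() -> None:
        nonlocal start, last_above_end, above_ct
        if start >= 0 and above_ct >= params.min_above_minutes:
            bouts.append(Bout(start, last_above_end, above_ct))
        start, last_above_end, above_ct = -1, -1, 0

    for is_above, is_worn, s, e in segs:
        if not is_worn:  # non-wear terminates immediately
            close()
        elif is_above:
            if start < 0:
                start = s
            above_ct += e - s
            last_above_end = e
        else:  # below-threshold wear run
            if start >= 0 and e - s > params.max_interruption_run:
                close()
    close()  # day end
    return bouts


def bout_minutes(bouts: Iterable[Bout]) -> int:
    """Credited minutes: above-threshold minutes summed over bouts."""
    return sum(b.above_minutes for b in bouts)


def meets_guideline(
    daily_bout_minutes: Sequence[tuple[int, int, bool]],
    params: BoutParams = BoutParams(),
) -> bool | None:
    """Evaluate the 30-minutes-on-5-of-7-days guideline on observed days.

    ``daily_bout_minutes`` holds (day_index, bout_minutes, valid_day)
    triples.  Returns None (undefined) when no day is valid.  Participants
    monitored for fewer than ``window_days`` days are evaluated on the days
    they have, which biases achievement low for short-wear participants.
    """
    valid = [(d, m) for d, m, ok in daily_bout_minutes if ok]
    if not valid:
        return None
    hit_days = sum(1 for _, m in valid if m >= params.daily_target)
    return hit_days >= params.days_target
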