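"""Wear / non-wear detection from runs of zero activity counts.

Non-wear is inferred from maximal runs of consecutive zero-count minutes of
length >= ``min_zero_run`` (default 60), the rule used for NHANES
accelerometer processing.  Runs never span day boundaries because data are
processed day-wise.  An optional interruption allowance (default off) lets a
run absorb short bursts of low counts, for sensitivity analyses mirroring
the NCI macro's tolerant variant; with the allowance active a non-wear run
may contain the interrupting minutes, so the all-zero invariant applies to
the default configuration only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import MINUTES_PER_DAY, EpochDay


@dataclass(frozen=True)
class WearMask:
    """Per-minute worn labels plus the maximal non-wear runs behind them."""

    worn: np.ndarray  # bool, length 1440
    nonwear_runs: tuple[tuple[int, int], ...]  # disjoint, sorted, half-open

    def __post_init__(self) -> None:
        worn = np.asarray(self.worn, dtype=bool)
        if worn.shape != (MINUTES_PER_DAY,):
            raise ValueError("worn must have length 1440")
        object.__setattr__(self, "worn", worn)
        object.__setattr__(self, "nonwear_runs", tuple(self.nonwear_runs))


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean array."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_nonwear(
    day: EpochDay,
    min_zero_run: int = 60,
    *,
    max_interruption: int = 0,
    interruption_ceiling: int = 100,
) -> WearMask:
    """Label each minute worn/not-worn from zero-count runs.

    A minute is non-wear iff it lies in a maximal run of consecutive
    zero-count minutes of length >= ``min_zero_run``.  With
    ``max_interruption`` > 0, zero runs separated by interruptions of at
    most ``max_interruption`` consecutive minutes, each with
    0 < counts < ``interruption_ceiling``, are merged before the length
    test (the merged run must still start and end on zero minutes).
    """
    if min_zero_run < 1:
        raise ValueError("min_zero_run must be >= 1")
    counts = day.counts
    zero = counts == 0
    zero_runs = _runs_of(zero)
    if max_interruption > 0:
        merged: list[tuple[int, int]] = []
        for start, end in zero_runs:
            if merged:
                pstart, pend = merged[-1]
                gap = counts[pend:start]
                if (
                    start - pend <= max_interruption
                    and (gap < interruption_ceiling).all()
                ):
                    merged[-1] = (pstart, end)
                    continue
            merged.append((start, end))
        zero_runs = merged
    nonwear = [(s, e) for s, e in zero_runs if e - s >= min_zero_run]
    worn = np.ones(MINUTES_PER_DAY, dtype=bool)
    for s, e in nonwear:
        worn[s:e] = False
    return WearMask(worn=worn, nonwear_runs=tuple(nonwear))


def wear_minutes(mask: WearMask) -> int:
    """Worn minutes in the day; worn + non-worn always totals 1,440."""
    return int(mask.worn.sum())


def nonwear_minutes(mask: WearMask) -> int:
    return MINUTES_PER_DAY - wear_minutes(mask)


def is_valid_day(mask: WearMask, min_wear: int = 600) -> bool:
    """A valid day has at least ``min_wear`` minutes of wear (>= 10 h)."""
    return wear_minutes(mask) >= min_wear
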