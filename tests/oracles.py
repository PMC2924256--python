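"""Brute-force reference implementations, deliberately naive and written
independently of the package internals (explicit per-minute scans instead
of run-length encoding / vectorization)."""

from itertools import groupby


def oracle_nonwear_worn(counts, min_run: int) -> list[bool]:
    """Worn flags from an explicit group-by scan for zero runs >= min_run."""
    worn = [True] * len(counts)
    i = 0
    for is_zero, grp in groupby(counts, key=lambda v: v == 0):
        length = len(list(grp))
        if is_zero and length >= min_run:
            for j in range(i, i + length):
                worn[j] = False
        i += length
    return worn


def oracle_breaks(counts, worn, bound: int = 100) -> int:
    """Pair scan for sedentary-to-active transitions within wear."""
    n = 0
    for t in range(len(counts) - 1):
        if worn[t] and worn[t + 1] and counts[t] < bound <= counts[t + 1]:
            n += 1
    return n


def oracle_time_tally(counts, worn, bins=(100, 500, 2020, 6000)) -> dict[str, int]:
    names = ("sedentary", "low", "light", "moderate", "vigorous")
    tally = {"nonwear": 0, **{k: 0 for k in names}}
    for c, w in zip(counts, worn):
        if not w:
            tally["nonwear"] += 1
            continue
        k = 0
        while k < len(bins) and c >= bins[k]:
            k += 1
        tally[names[k]] += 1
    return tally


def oracle_bouts(counts, worn, params) -> list[tuple[int, int, int]]:
    """Candidate-interval scan applying the interruption/termination rules
    minute by minute; returns (start, end, above_minutes) triples."""
    n = len(counts)
    above = [worn[i] and counts[i] >= params.threshold for i in range(n)]
    bouts = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j, below, above_ct, last = i, 0, 0, i
        while j < n and worn[j]:
            if above[j]:
                above_ct += 1
                last = j
                below = 0
            else:
                below += 1
                if below > params.max_interruption_run:
                    break
            j += 1
        if above_ct >= params.min_above_minutes:
            bouts.append((i, last + 1, above_ct))
            i = last + 1
        else:
            i += 1
    return bouts
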