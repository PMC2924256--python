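import numpy as np
import pytest

from actiprofile.epochs import MINUTES_PER_DAY, EpochDay

# count palette concentrated on band boundaries so random days exercise
# every cut-point edge (0/99/100/499/500/2019/2020/5999/6000)
PALETTE = np.array(
    [0, 0, 0, 1, 50, 99, 100, 250, 499, 500, 1000, 2019, 2020, 3000, 5999, 6000, 9000, 15000],
    dtype=np.int64,
)


def random_counts(rng: np.random.Generator) -> np.ndarray:
    """Structured random day: a mix of zero runs, constant runs and noise."""
    parts, total = [], 0
    while total < MINUTES_PER_DAY:
        kind = int(rng.integers(3))
        if kind == 0:
            length = int(rng.integers(1, 200))
            v = np.zeros(length, dtype=np.int64)
        elif kind == 1:
            length = int(rng.integers(1, 30))
            v = np.full(length, PALETTE[rng.integers(len(PALETTE))], dtype=np.int64)
        else:
            length = int(rng.integers(1, 30))
            v = rng.choice(PALETTE, size=length)
        parts.append(v)
        total += len(v)
    return np.concatenate(parts)[:MINUTES_PER_DAY]


def random_day(rng: np.random.Generator, pid: str = "R", day: int = 1) -> EpochDay:
    counts = random_counts(rng)
    steps = rng.integers(0, 120, size=MINUTES_PER_DAY)
    steps[counts == 0] = 0
    return EpochDay(participant_id=pid, day_index=day, counts=counts, steps=steps)


def make_day(counts, pid: str = "T", day: int = 1, steps=None) -> EpochDay:
    """Pad a short counts prefix with zeros to a full 1,440-minute day."""
    c = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    c[: len(counts)] = counts
    s = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    if steps is not None:
        s[: len(steps)] = steps
    return EpochDay(participant_id=pid, day_index=day, counts=c, steps=s)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
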