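"""Minute-epoch accelerometer data: containers and readers/writers.

The canonical on-disk format is a long CSV with one row per
participant-minute (``participant_id, day_index, minute_of_day, counts,
steps``).  An NHANES PAXRAW-style dialect (SAS transport with sequential
minute numbering) is supported through a thin adapter.

Minutes are indexed 0..1439 within a day and all intervals throughout the
package are half-open ``[start, end)``.  Minutes absent from an input file
are filled with zero counts and zero steps — the NHANES convention for
unrecorded time — and every fill is logged.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

CANONICAL_EPOCH_COLUMNS = (
    "participant_id",
    "day_index",
    "minute_of_day",
    "counts",
    "steps",
)

PARTICIPANT_COLUMNS = (
    "participant_id",
    "bmi",
    "sex",
    "age_years",
    "survey_weight",
    "stratum_id",
    "psu_id",
    "reliable_flag",
    "calibrated_flag",
    "pregnant_flag",
)


@dataclass(frozen=True)
class EpochDay:
    """One participant-day of minute-epoch data.

    ``counts`` and ``steps`` are aligned int64 arrays of length 1,440
    (activity counts/minute and steps/minute).
    """

    participant_id: str
    day_index: int
    counts: np.ndarray
    steps: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        steps = np.asarray(self.steps, dtype=np.int64)
        if counts.shape != (MINUTES_PER_DAY,) or steps.shape != (MINUTES_PER_DAY,):
            raise ValueError(
                f"EpochDay requires {MINUTES_PER_DAY} counts and steps; "
                f"got {len(counts)} counts / {len(steps)} steps for "
                f"({self.participant_id!r}, day {self.day_index})"
            )
        if (counts < 0).any() or (steps < 0).any():
            raise ValueError(
                f"negative counts/steps in ({self.participant_id!r}, "
                f"day {self.day_index})"
            )
        if self.day_index < 1:
            raise ValueError("day_index must be >= 1")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "steps", steps)


@dataclass(frozen=True)
class ParticipantRecord:
    """Participant metadata needed for profiling and survey estimation."""

    participant_id: str
    bmi: float  # kg/m^2; NaN when missing
    sex: str  # "male" | "female"
    age_years: float
    survey_weight: float
    stratum_id: str
    psu_id: str
    reliable_flag: bool = True
    calibrated_flag: bool = True
    pregnant_flag: bool = False

    def __post_init__(self) -> None:
        if not (self.survey_weight > 0):
            raise ValueError(
                f"survey_weight must be > 0 for {self.participant_id!r}"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


class EpochReadResult(NamedTuple):
    days: list[EpochDay]
    fill_log: pd.DataFrame  # columns: participant_id, day_index, minute_of_day


def _frame_to_days(df: pd.DataFrame) -> EpochReadResult:
    """Assemble (participant, day) groups into EpochDays, zero-filling gaps."""
    dup = df.duplicated(subset=["participant_id", "day_index", "minute_of_day"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicate epoch for key (participant_id="
            f"{row['participant_id']!r}, day_index={int(row['day_index'])}, "
            f"minute_of_day={int(row['minute_of_day'])})"
        )
    for col in ("counts", "steps"):
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            frac = vals != np.floor(vals)
            if frac.any():
                rownum = int(np.nonzero(frac)[0][0])
                raise ValueError(f"non-integer {col} at input row {rownum}")
        if (vals < 0).any():
            rownum = int(np.nonzero(vals < 0)[0][0])
            raise ValueError(f"negative {col} at input row {rownum}")
    minute = df["minute_of_day"].to_numpy()
    if ((minute < 0) | (minute >= MINUTES_PER_DAY)).any():
        rownum = int(np.nonzero((minute < 0) | (minute >= MINUTES_PER_DAY))[0][0])
        raise ValueError(f"minute_of_day out of range [0, 1440) at input row {rownum}")

    days: list[EpochDay] = []
    filled: list[tuple[str, int, int]] = []
    # sort so output is independent of input row order
    for (pid, day_index), grp in sorted(
        df.groupby(["participant_id", "day_index"], sort=False),
        key=lambda kv: (str(kv[0][0]), int(kv[0][1])),
    ):
        counts = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
        steps = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
        mins = grp["minute_of_day"].to_numpy(dtype=np.int64)
        counts[mins] = grp["counts"].to_numpy(dtype=np.int64)
        steps[mins] = grp["steps"].to_numpy(dtype=np.int64)
        present = np.zeros(MINUTES_PER_DAY, dtype=bool)
        present[mins] = True
        for m in np.nonzero(~present)[0]:
            filled.append((str(pid), int(day_index), int(m)))
        days.append(
            EpochDay(
                participant_id=str(pid),
                day_index=int(day_index),
                counts=counts,
                steps=steps,
            )
        )
    fill_log = pd.DataFrame(
        filled, columns=["participant_id", "day_index", "minute_of_day"]
    )
    return EpochReadResult(days, fill_log)


def paxraw_frame_to_days(df: pd.DataFrame) -> EpochReadResult:
    """Map a PAXRAW-style table onto the canonical layout.

    Expects columns SEQN (participant), PAXN (sequential minute, 1-based
    across the whole monitoring period), PAXINTEN (counts) and PAXSTEP
    (steps).  PAXN n belongs to day ``(n-1)//1440 + 1``, minute
    ``(n-1) % 1440``.
    """
    required = {"SEQN", "PAXN", "PAXINTEN", "PAXSTEP"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PAXRAW input missing columns: {sorted(missing)}")
    n = df["PAXN"].to_numpy(dtype=np.int64)
    canonical = pd.DataFrame(
        {
            "participant_id": df["SEQN"].astype(np.int64).astype(str),
            "day_index": (n - 1) // MINUTES_PER_DAY + 1,
            "minute_of_day": (n - 1) % MINUTES_PER_DAY,
            "counts": df["PAXINTEN"].to_numpy(),
            "steps": df["PAXSTEP"].to_numpy(),
        }
    )
    return _frame_to_days(canonical)


def read_epoch_table(path: str | Path, dialect: str = "canonical-csv") -> EpochReadResult:
    """Read minute-epoch data into EpochDays plus a fill log.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"canonical-csv"`` (long CSV, see module docstring) or
        ``"paxraw-xpt"`` (SAS transport in the NHANES PAXRAW layout).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "canonical-csv":
        df = pd.read_csv(path, dtype={"participant_id": str})
        missing = set(CANONICAL_EPOCH_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"epoch CSV missing columns: {sorted(missing)}")
        return _frame_to_days(df)
    if dialect == "paxraw-xpt":
        df = pd.read_sas(path, format="xport")
        return paxraw_frame_to_days(df)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_epoch_table(days: Iterable[EpochDay], path: str | Path) -> None:
    """Write EpochDays as the canonical long CSV (1,440 rows per day)."""
    days = list(days)
    if not days:
        raise ValueError("no EpochDays to write")
    minute = np.arange(MINUTES_PER_DAY)
    frames = [
        pd.DataFrame(
            {
                "participant_id": d.participant_id,
                "day_index": d.day_index,
                "minute_of_day": minute,
                "counts": d.counts,
                "steps": d.steps,
            }
        )
        for d in days
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_participant_table(path: str | Path) -> list[ParticipantRecord]:
    """Read the participant metadata CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str, "stratum_id": str, "psu_id": str})
    missing = set(PARTICIPANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"participant CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        bmi = row["bmi"]
        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                bmi=float(bmi) if pd.notna(bmi) else math.nan,
                sex=str(row["sex"]),
                age_years=float(row["age_years"]),
                survey_weight=float(row["survey_weight"]),
                stratum_id=str(row["stratum_id"]),
                psu_id=str(row["psu_id"]),
                reliable_flag=bool(row["reliable_flag"]),
                calibrated_flag=bool(row["calibrated_flag"]),
                pregnant_flag=bool(row["pregnant_flag"]),
            )
        )
    return records


def write_participant_table(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    records = list(records)
    if not records:
        raise ValueError("no ParticipantRecords to write")
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def profiles_to_frame(profiles: Sequence) -> pd.DataFrame:
    """Tidy table with one row per profile (DayProfile or ParticipantProfile)."""
    if len(profiles) == 0:
        raise ValueError("no profiles to convert")
    return pd.DataFrame([dataclasses.asdict(p) for p in profiles])


def write_profiles(profiles: Sequence, path: str | Path) -> None:
    """Write profiles as a tidy CSV, one row per profile.

    Column names are the dataclass field names and are stable across
    releases; values round-trip through ``pandas.read_csv`` at full
    precision.
    """
    profiles_to_frame(profiles).to_csv(path, index=False)
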