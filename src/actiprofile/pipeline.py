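"""End-to-end drivers tying the per-day, per-participant and cohort stages
together under one RunConfig."""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from .cohort import CohortSummary, InclusionReport, apply_inclusion, summarize_cohort
from .config import RunConfig
from .day_metrics import DayProfile, profile_day
from .epochs import EpochDay, ParticipantRecord
from .participants import ExclusionError, ParticipantProfile, aggregate_participant
from .wear import detect_nonwear


def profile_days(days: Iterable[EpochDay], config: RunConfig = RunConfig()) -> list[DayProfile]:
    """Per-day indicator profiles for every EpochDay."""
    out = []
    for day in days:
        mask = detect_nonwear(day, config.wear.min_zero_run)
        out.append(
            profile_day(
                day,
                config.cutpoints,
                min_zero_run=config.wear.min_zero_run,
                min_wear=config.wear.min_wear_minutes,
                censor_below=config.censor_below,
                bout_params=config.bouts,
                mask=mask,
            )
        )
    return out


def profile_participants(
    day_profiles: Sequence[DayProfile],
    records: Sequence[ParticipantRecord] | None = None,
    config: RunConfig = RunConfig(),
) -> tuple[dict[str, ParticipantProfile], dict[str, str]]:
    """Aggregate day profiles per participant.

    Returns (profiles by id, exclusion reasons by id); participants whose
    days never reach the validity threshold land in the second map.
    """
    bmi_of = {r.participant_id: r.bmi for r in records} if records else {}
    by_pid: dict[str, list[DayProfile]] = defaultdict(list)
    for dp in day_profiles:
        by_pid[dp.participant_id].append(dp)
    profiles: dict[str, ParticipantProfile] = {}
    dropped: dict[str, str] = {}
    for pid, days in by_pid.items():
        try:
            profiles[pid] = aggregate_participant(
                days,
                config.aggregate.averaging,
                bout_params=config.bouts,
                step_bounds=config.steplevel_bounds,
                bmi=bmi_of.get(pid),
            )
        except ExclusionError as exc:
            dropped[pid] = exc.reason
    return profiles, dropped


def run_pipeline(
    days: Iterable[EpochDay],
    records: Sequence[ParticipantRecord],
    config: RunConfig = RunConfig(),
) -> tuple[CohortSummary, InclusionReport, dict[str, ParticipantProfile]]:
    """Raw epochs + participant table -> weighted cohort summary."""
    dps = profile_days(days, config)
    profiles, _ = profile_participants(dps, records, config)
    paired = [(rec, profiles.get(rec.participant_id)) for rec in records]
    analyzed, report = apply_inclusion(paired)
    summary = summarize_cohort(
        analyzed,
        include_underweight=config.summary.include_underweight,
        ci_multiplier=config.summary.ci_multiplier,
        single_psu=config.summary.single_psu,
        adjust_for_wear=config.summary.adjust_for_wear,
    )
    return summary, report, profiles
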