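"""Synthetic minute-epoch cohorts with exact, construction-time ground truth.

The generator emulates the statistical structure the profiling pipeline
assumes: 1,440-minute days; non-wear as scheduled long zero runs; an
i.i.d. intensity mixture over the NHANES count bands within wear;
count-coupled Poisson step emission (steps are zero whenever counts are
zero); optional injected MVPA bouts with short interruptions; and a
participant table with BMI category, sex, survey weight and design
variables.  Default parameter values reproduce the population conditions
of the 2005-2006 U.S. adult accelerometer sample: wear-time intensity
shares of 56.8 / 23.7 / 16.7 / 2.6 / 0.2 percent (sedentary through
vigorous), BMI-category prevalences from the analyzed sample, a ~3.2%
guideline-achiever fraction, and a decreasing activity gradient from
normal weight to obese.

Two construction guards keep the emitted ground truth exact rather than
approximate: wear minutes are resampled so that no zero run of >= 60
minutes can arise inside (or at the edge of) a scheduled wear block, and
background moderate/vigorous minutes are demoted to light whenever they
would accumulate into a qualifying 10-minute bout, so the only bouts in a
generated day are the injected ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .bouts import BoutParams
from .day_metrics import MINUTES_PER_DAY, DayProfile, Intensity
from .epochs import (
    EpochDay,
    ParticipantRecord,
    write_epoch_table,
    write_participant_table,
    write_profiles,
)
from .participants import (
    DEFAULT_STEP_BOUNDS,
    ParticipantProfile,
    bmi_category,
    classify_step_level,
)

_CLASS_NAMES = ("sedentary", "low", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class BoutInjection:
    """One injected bout: start minute and alternating above/below segment
    lengths, beginning and ending with an above-threshold segment."""

    start: int
    segments: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.segments) % 2 == 0 or not self.segments:
            raise ValueError("segments must alternate above/below and end above")
        if any(s < 1 for s in self.segments):
            raise ValueError("segment lengths must be >= 1")

    @property
    def span(self) -> int:
        return sum(self.segments)

    @property
    def above_total(self) -> int:
        return sum(self.segments[::2])


@dataclass(frozen=True)
class SimSpec:
    """Full description of a synthetic cohort; the seed determines everything."""

    n_participants: int = 50
    days_per_participant: int = 7
    wear_blocks: tuple[tuple[int, int], ...] = ((480, 1195),)  # 715 min worn
    intensity_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "sedentary": 0.568,
            "low": 0.237,
            "light": 0.167,
            "moderate": 0.026,
            "vigorous": 0.002,
        }
    )
    steps_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "sedentary": 1.0,
            "low": 16.0,
            "light": 41.0,
            "moderate": 80.0,
            "vigorous": 105.0,
        }
    )
    sedentary_zero_prob: float = 0.3
    vigorous_max: int = 15000
    bout_params: BoutParams = BoutParams()
    # guideline achievers: fraction of participants injected with a daily
    # qualifying bout (32 above-threshold minutes, one 2-minute interruption)
    p_bouter: float = 0.032
    bouter_injections: tuple[BoutInjection, ...] = (
        BoutInjection(start=600, segments=(16, 2, 16)),
    )
    p_no_wear_day: float = 0.0
    # BMI model: category prevalences of the analyzed adult sample and
    # uniform within-category BMI values
    bmi_category_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "underweight": 69 / 3522,
            "normal": 1016 / 3522,
            "overweight": 1195 / 3522,
            "obese": 1242 / 3522,
        }
    )
    bmi_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "underweight": (16.0, 18.5),
            "normal": (18.5, 25.0),
            "overweight": (25.0, 30.0),
            "obese": (30.0, 45.0),
        }
    )
    # activity gradient across BMI categories (multiplies step-rate means
    # and the moderate/vigorous mixture mass); ratios follow the observed
    # censored-steps/day gradient about the overall mean
    category_activity_scale: Mapping[str, float] = field(
        default_factory=lambda: {
            "underweight": 1.10,
            "normal": 1.10,
            "overweight": 1.05,
            "obese": 0.88,
        }
    )
    p_male: float = 0.5
    weight_scale: float = 20000.0
    weight_sigma: float = 0.6
    n_strata: int = 15
    p_unreliable: float = 0.0
    p_uncalibrated: float = 0.0
    p_pregnant: float = 0.0
    min_zero_run: int = 60
    min_wear: int = 600
    censor_below: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.intensity_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"intensity_mix must sum to 1, got {total}")
        blocks = sorted(self.wear_blocks)
        for (s, e) in blocks:
            if not (0 <= s < e <= MINUTES_PER_DAY):
                raise ValueError(f"bad wear block [{s}, {e})")
        for (_, e1), (s2, _) in zip(blocks[:-1], blocks[1:]):
            if s2 < e1:
                raise ValueError("wear blocks must be disjoint")


@dataclass
class SimulatedCohort:
    spec: SimSpec
    days: list[EpochDay]
    records: list[ParticipantRecord]
    truth_day_profiles: list[DayProfile]
    truth_participant_profiles: list[ParticipantProfile]


_BAND_LOW = np.array([0, 100, 500, 2020, 6000], dtype=np.int64)


def _band_high(spec: SimSpec) -> np.ndarray:
    return np.array([100, 500, 2020, 6000, spec.vigorous_max + 1], dtype=np.int64)


def generate_day(
    spec: SimSpec,
    participant_id: str,
    day_index: int,
    rng: np.random.Generator,
    *,
    injections: Sequence[BoutInjection] = (),
    activity_scale: float = 1.0,
    no_wear: bool = False,
) -> tuple[EpochDay, DayProfile]:
    """Generate one participant-day plus its exact ground-truth profile.

    The truth profile is computed from the construction (sampled class
    labels, scheduled wear, injected bout patterns), never by running the
    analysis pipeline.
    """
    counts = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    steps = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    cls = np.zeros(MINUTES_PER_DAY, dtype=np.int8)  # 0 = nonwear

    bp = spec.bout_params
    mix = np.array([spec.intensity_mix[c] for c in _CLASS_NAMES], dtype=float)
    # shift mixture mass between moderate+vigorous and sedentary to impose
    # the per-category activity gradient
    mix = mix.copy()
    mvpa = mix[3:].sum()
    mix[3:] *= activity_scale
    mix[0] += mvpa - mix[3:].sum()
    mix /= mix.sum()
    smeans = np.array(
        [spec.steps_mean[c] * activity_scale for c in _CLASS_NAMES], dtype=float
    )
    high = _band_high(spec)

    blocks = () if no_wear else tuple(sorted(spec.wear_blocks))
    for (bs, be) in blocks:
        L = be - bs
        c = rng.choice(5, size=L, p=mix).astype(np.int8) + 1  # 1..5
        val = rng.integers(_BAND_LOW[c - 1], high[c - 1])
        sed = c == Intensity.SEDENTARY
        nsed = int(sed.sum())
        if nsed:
            zero = rng.random(nsed) < spec.sedentary_zero_prob
            sedvals = rng.integers(1, 100, size=nsed)
            sedvals[zero] = 0
            val[sed] = sedvals
        # guard 1: background MVPA minutes must never accumulate into a bout
        above_pos = np.nonzero(c >= Intensity.MODERATE)[0]
        accum, prev = 0, None
        for p in above_pos.tolist():
            if prev is not None and (p - prev - 1) > bp.max_interruption_run:
                accum = 0
            if accum >= bp.min_above_minutes - 1:
                c[p] = Intensity.LIGHT  # demote; prev stays at last kept above
                val[p] = rng.integers(500, 2020)
                continue
            accum += 1
            prev = p
        # guard 2: no zero run >= min_zero_run may touch the wear block
        if val[0] == 0:
            val[0] = rng.integers(1, 100)
        if val[L - 1] == 0:
            val[L - 1] = rng.integers(1, 100)
        zero_idx = np.nonzero(val == 0)[0]
        if len(zero_idx) >= spec.min_zero_run:
            run_start = 0
            run_len = 0
            prev_i = -2
            for i in zero_idx.tolist() + [-1]:
                if i == prev_i + 1:
                    run_len += 1
                else:
                    run_len = 1
                    run_start = i
                if run_len >= spec.min_zero_run:
                    val[i] = rng.integers(1, 100)
                    run_len = 0
                prev_i = i
        counts[bs:be] = val
        cls[bs:be] = c

    truth_bout_minutes = 0
    for inj in sorted(injections, key=lambda i: i.start):
        # locate the containing wear block; crossing into non-wear is an error
        block = next(((s, e) for s, e in blocks if s <= inj.start and inj.start + inj.span <= e), None)
        if block is None:
            raise ValueError(
                f"injected bout at {inj.start} (span {inj.span}) does not fit a wear block"
            )
        below_ok = all(s <= bp.max_interruption_run for s in inj.segments[1::2])
        pos = inj.start
        for k, seg in enumerate(inj.segments):
            if k % 2 == 0:  # above-threshold segment
                counts[pos : pos + seg] = rng.integers(max(bp.threshold, 2020), 6000, size=seg)
                cls[pos : pos + seg] = Intensity.MODERATE
            else:  # interruption segment, kept below the sedentary bound
                counts[pos : pos + seg] = rng.integers(1, 100, size=seg)
                cls[pos : pos + seg] = Intensity.SEDENTARY
            pos += seg
        # buffer: force the closure rule on both sides so background MVPA
        # cannot extend the injected bout
        for lo, hi in (
            (max(block[0], inj.start - bp.termination_run), inj.start),
            (pos, min(block[1], pos + bp.termination_run)),
        ):
            for m in range(lo, hi):
                if cls[m] >= Intensity.MODERATE:
                    cls[m] = Intensity.LIGHT
                    counts[m] = rng.integers(500, 2020)
        if below_ok and inj.above_total >= bp.min_above_minutes:
            truth_bout_minutes += inj.above_total

    wear_mask = cls > 0
    n_wear = int(wear_mask.sum())
    if n_wear:
        lam = smeans[cls[wear_mask] - 1]
        s = rng.poisson(lam)
        s[counts[wear_mask] == 0] = 0
        steps[wear_mask] = s

    # ground truth from the construction
    tally = np.bincount(cls, minlength=6)
    sed_pair = (cls[:-1] == Intensity.SEDENTARY) & (cls[1:] >= Intensity.LOW)
    censored = int(steps[cls >= Intensity.LIGHT].sum())
    truth = DayProfile(
        participant_id=participant_id,
        day_index=day_index,
        wear_minutes=n_wear,
        nonwear_minutes=MINUTES_PER_DAY - n_wear,
        activity_counts_total=int(counts.sum()),
        steps_uncensored=int(steps.sum()),
        steps_censored=censored,
        minutes_sedentary=int(tally[Intensity.SEDENTARY]),
        minutes_low=int(tally[Intensity.LOW]),
        minutes_light=int(tally[Intensity.LIGHT]),
        minutes_moderate=int(tally[Intensity.MODERATE]),
        minutes_vigorous=int(tally[Intensity.VIGOROUS]),
        breaks=int(sed_pair.sum()),
        mvpa_bout_minutes=truth_bout_minutes,
        valid=n_wear >= spec.min_wear,
    )
    day = EpochDay(participant_id=participant_id, day_index=day_index, counts=counts, steps=steps)
    return day, truth


def _truth_participant(
    spec: SimSpec,
    pid: str,
    truths: Sequence[DayProfile],
    bmi: float,
) -> ParticipantProfile | None:
    """Participant-level truth by direct arithmetic over valid-day truths."""
    worn = [t for t in truths if t.wear_minutes > 0]
    valid = [t for t in truths if t.valid]
    if not valid:
        return None

    def mean(attr: str) -> float:
        return sum(getattr(t, attr) for t in valid) / len(valid)

    def mean_rate(attr: str) -> float:
        return sum(getattr(t, attr) / t.wear_minutes for t in valid) / len(valid)

    hit = sum(1 for t in valid if t.mvpa_bout_minutes >= spec.bout_params.daily_target)
    mean_cens = mean("steps_censored")
    return ParticipantProfile(
        participant_id=pid,
        n_days_worn=len(worn),
        n_valid_days=len(valid),
        mean_wear_minutes=mean("wear_minutes"),
        mean_nonwear_minutes=mean("nonwear_minutes"),
        mean_activity_counts=mean("activity_counts_total"),
        mean_steps_uncensored=mean("steps_uncensored"),
        mean_steps_censored=mean_cens,
        mean_minutes_sedentary=mean("minutes_sedentary"),
        mean_minutes_low=mean("minutes_low"),
        mean_minutes_light=mean("minutes_light"),
        mean_minutes_moderate=mean("minutes_moderate"),
        mean_minutes_vigorous=mean("minutes_vigorous"),
        mean_breaks=mean("breaks"),
        mean_mvpa_bout_minutes=mean("mvpa_bout_minutes"),
        mean_counts_per_min=mean_rate("activity_counts_total"),
        mean_steps_uncensored_per_min=mean_rate("steps_uncensored"),
        mean_steps_censored_per_min=mean_rate("steps_censored"),
        guideline_met=hit >= spec.bout_params.days_target,
        step_level=classify_step_level(mean_cens, DEFAULT_STEP_BOUNDS),
        bmi_category=bmi_category(bmi),
    )


def generate_cohort(spec: SimSpec) -> SimulatedCohort:
    """Generate a full cohort: epoch days, participant records, and exact
    ground-truth day- and participant-level profiles."""
    rng = np.random.default_rng(spec.seed)
    cats = list(spec.bmi_category_probs)
    cat_p = np.array([spec.bmi_category_probs[c] for c in cats], dtype=float)
    cat_p = cat_p / cat_p.sum()

    days: list[EpochDay] = []
    records: list[ParticipantRecord] = []
    truth_days: list[DayProfile] = []
    truth_parts: list[ParticipantProfile] = []

    for i in range(spec.n_participants):
        pid = f"P{i + 1:05d}"
        cat = cats[int(rng.choice(len(cats), p=cat_p))]
        lo, hi = spec.bmi_ranges[cat]
        bmi = float(rng.uniform(lo, hi))
        sex = "male" if rng.random() < spec.p_male else "female"
        weight = float(spec.weight_scale * rng.lognormal(0.0, spec.weight_sigma))
        stratum = f"S{int(rng.integers(spec.n_strata)) + 1:02d}"
        psu = f"PSU{int(rng.integers(2)) + 1}"
        pregnant = sex == "female" and rng.random() < spec.p_pregnant
        rec = ParticipantRecord(
            participant_id=pid,
            bmi=bmi,
            sex=sex,
            age_years=float(rng.uniform(20, 80)),
            survey_weight=weight,
            stratum_id=stratum,
            psu_id=psu,
            reliable_flag=rng.random() >= spec.p_unreliable,
            calibrated_flag=rng.random() >= spec.p_uncalibrated,
            pregnant_flag=pregnant,
        )
        records.append(rec)
        scale = spec.category_activity_scale[cat]
        bouter = rng.random() < spec.p_bouter
        my_truths: list[DayProfile] = []
        for d in range(1, spec.days_per_participant + 1):
            no_wear = rng.random() < spec.p_no_wear_day
            day, truth = generate_day(
                spec,
                pid,
                d,
                rng,
                injections=spec.bouter_injections if (bouter and not no_wear) else (),
                activity_scale=scale,
                no_wear=no_wear,
            )
            days.append(day)
            truth_days.append(truth)
            my_truths.append(truth)
        tp = _truth_participant(spec, pid, my_truths, bmi)
        if tp is not None:
            truth_parts.append(tp)

    return SimulatedCohort(
        spec=spec,
        days=days,
        records=records,
        truth_day_profiles=truth_days,
        truth_participant_profiles=truth_parts,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write canonical CSVs plus ground truth and the resolved spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_epoch_table(cohort.days, outdir / "epochs.csv")
    write_participant_table(cohort.records, outdir / "participants.csv")
    write_profiles(cohort.truth_day_profiles, outdir / "truth_day_profiles.csv")
    write_profiles(cohort.truth_participant_profiles, outdir / "truth_participant_profiles.csv")
    resolved = dataclasses.asdict(cohort.spec)
    resolved["intensity_mix"] = dict(cohort.spec.intensity_mix)
    resolved["steps_mean"] = dict(cohort.spec.steps_mean)
    (outdir / "sim_spec.json").write_text(json.dumps(resolved, indent=2, default=str))
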