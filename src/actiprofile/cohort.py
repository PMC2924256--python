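"""Cohort-level estimation: inclusion cascade, survey-weighted summaries,
and trend tests across BMI categories.

Weighted means use the ratio estimator sum(w*x)/sum(w) with a standard
stratified-cluster Taylor-linearized standard error (with-replacement PSU
approximation).  When no design variables are supplied, the whole sample is
one stratum with each unit its own PSU, which reduces to the familiar
weighted-ratio linearized SE.  Trend tests regress an indicator on the
ordinal BMI-category code (0 = normal, 1 = overweight, 2 = obese) by
survey-weighted least squares with a sandwich covariance (PSU-clustered
when a design is given), optionally adjusting for wear time as a covariate.
Confidence intervals use a normal multiplier (1.96) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .epochs import ParticipantRecord
from .participants import BMI_CATEGORIES, STEP_LEVELS, ParticipantProfile

# participant-level indicators summarized in cohort tables
SUMMARY_INDICATORS = (
    "mean_activity_counts",
    "mean_steps_uncensored",
    "mean_steps_censored",
    "mean_counts_per_min",
    "mean_steps_uncensored_per_min",
    "mean_steps_censored_per_min",
    "mean_wear_minutes",
    "mean_nonwear_minutes",
    "mean_minutes_sedentary",
    "mean_minutes_low",
    "mean_minutes_light",
    "mean_minutes_moderate",
    "mean_minutes_vigorous",
    "mean_breaks",
    "mean_mvpa_bout_minutes",
)

EXCLUSION_ORDER = (
    "unreliable",
    "uncalibrated",
    "pregnant",
    "bmi_gt_100",
    "no_valid_day",
)


@dataclass(frozen=True)
class InclusionReport:
    """Counts at each stage of the exclusion cascade.

    Each participant is assigned to the first failing rule only, in the
    order unreliable -> uncalibrated -> pregnant -> BMI > 100 -> no valid
    day; the bucket counts always conserve the eligible total.
    """

    eligible: int
    excluded_unreliable: int
    excluded_uncalibrated: int
    excluded_pregnant: int
    excluded_bmi_gt_100: int
    excluded_no_valid_day: int
    analyzed: int

    def __post_init__(self) -> None:
        total = (
            self.excluded_unreliable
            + self.excluded_uncalibrated
            + self.excluded_pregnant
            + self.excluded_bmi_gt_100
            + self.excluded_no_valid_day
            + self.analyzed
        )
        if total != self.eligible:
            raise ValueError("inclusion buckets do not conserve the eligible count")


@dataclass(frozen=True)
class TrendResult:
    slope: float
    se: float
    p_value: float
    adjusted_for_wear: bool


@dataclass
class CohortSummary:
    """Weighted cohort tables.

    means: one row per (indicator, sex, bmi_category) with weighted mean,
    SE and CI.  trends: one row per (indicator, sex).  step_levels /
    guideline: weighted percentage tables per (sex, bmi_category) cell.
    """

    means: pd.DataFrame
    trends: pd.DataFrame
    step_levels: pd.DataFrame
    guideline: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def apply_inclusion(
    participants: Sequence[tuple[ParticipantRecord, ParticipantProfile | None]],
) -> tuple[list[tuple[ParticipantRecord, ParticipantProfile]], InclusionReport]:
    """Apply the study's ordered exclusion cascade.

    ``participants`` pairs each eligible record with its profile, or with
    None when the participant had no valid day of wear.
    """
    buckets = {k: 0 for k in EXCLUSION_ORDER}
    analyzed: list[tuple[ParticipantRecord, ParticipantProfile]] = []
    for rec, prof in participants:
        if not rec.reliable_flag:
            buckets["unreliable"] += 1
        elif not rec.calibrated_flag:
            buckets["uncalibrated"] += 1
        elif rec.pregnant_flag:
            buckets["pregnant"] += 1
        elif not math.isnan(rec.bmi) and rec.bmi > 100:
            buckets["bmi_gt_100"] += 1
        elif prof is None or prof.n_valid_days < 1:
            buckets["no_valid_day"] += 1
        else:
            analyzed.append((rec, prof))
    report = InclusionReport(
        eligible=len(participants),
        excluded_unreliable=buckets["unreliable"],
        excluded_uncalibrated=buckets["uncalibrated"],
        excluded_pregnant=buckets["pregnant"],
        excluded_bmi_gt_100=buckets["bmi_gt_100"],
        excluded_no_valid_day=buckets["no_valid_day"],
        analyzed=len(analyzed),
    )
    return analyzed, report


def weighted_mean_se(
    values: Sequence[float],
    weights: Sequence[float],
    strata: Sequence | None = None,
    psus: Sequence | None = None,
    *,
    single_psu: str = "error",
) -> tuple[float, float]:
    """Survey-weighted mean with Taylor-linearized SE.

    With ``strata``/``psus`` omitted the design is one stratum with each
    unit its own PSU.  ``single_psu`` controls strata containing one PSU:
    ``"error"`` raises, ``"collapse"`` merges all single-PSU strata into
    one synthetic stratum before linearization.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("values and weights must be equal-length 1-D")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if strata is None:
        strata = np.zeros(len(x), dtype=int)
    if psus is None:
        psus = np.arange(len(x))
    strata = np.asarray(strata)
    psus = np.asarray(psus)

    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    # linearized score for the ratio estimator
    z = w * (x - mean) / wsum

    df = pd.DataFrame({"stratum": strata, "psu": psus, "z": z})
    psu_tot = df.groupby(["stratum", "psu"], sort=False)["z"].sum()
    n_psus = psu_tot.groupby(level="stratum").size()
    singles = n_psus[n_psus < 2].index
    if len(singles) > 0:
        if single_psu == "error":
            raise ValueError(
                f"strata with a single PSU: {list(singles)}; "
                "pass single_psu='collapse' to merge them"
            )
        if single_psu != "collapse":
            raise ValueError("single_psu must be 'error' or 'collapse'")
        relabel = psu_tot.index.get_level_values("stratum").isin(singles)
        collapsed = psu_tot[relabel]
        psu_tot = psu_tot[~relabel]
        merged = pd.Series(
            collapsed.to_numpy(),
            index=pd.MultiIndex.from_arrays(
                [["__collapsed__"] * len(collapsed), range(len(collapsed))],
                names=["stratum", "psu"],
            ),
        )
        psu_tot = pd.concat([psu_tot, merged])
        if len(merged) < 2:
            raise ValueError("cannot linearize: fewer than 2 PSUs after collapsing")

    var = 0.0
    for _, tot in psu_tot.groupby(level="stratum"):
        n_h = len(tot)
        zc = tot.to_numpy()
        var += n_h / (n_h - 1) * ((zc - zc.mean()) ** 2).sum()
    return mean, float(math.sqrt(var))


def trend_test(
    values: Sequence[float],
    weights: Sequence[float],
    category_codes: Sequence[int],
    covariates: pd.DataFrame | Sequence[float] | None = None,
    psus: Sequence | None = None,
) -> TrendResult:
    """Survey-weighted linear trend of an indicator across ordinal categories.

    Fits weighted least squares of the indicator on the category code
    (0, 1, 2, ...), optionally plus covariates (e.g. wear time), and tests
    the code's slope with a sandwich (HC1, or PSU-clustered) covariance.
    """
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    codes = np.asarray(category_codes, dtype=float)
    if len(np.unique(codes)) < 2:
        raise ValueError("trend test needs at least 2 categories")
    X = pd.DataFrame({"const": 1.0, "category_code": codes})
    adjusted = covariates is not None
    if adjusted:
        cov = pd.DataFrame(covariates)
        if cov.shape[1] == 1 and list(cov.columns) == [0]:
            cov.columns = ["covariate"]
        X = pd.concat([X, cov.reset_index(drop=True)], axis=1)
    model = sm.WLS(y, X, weights=w)
    if psus is not None:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(psus)})
    else:
        fit = model.fit(cov_type="HC1")
    return TrendResult(
        slope=float(fit.params["category_code"]),
        se=float(fit.bse["category_code"]),
        p_value=float(fit.pvalues["category_code"]),
        adjusted_for_wear=adjusted,
    )


def _analysis_frame(
    analyzed: Sequence[tuple[ParticipantRecord, ParticipantProfile]],
) -> pd.DataFrame:
    rows = []
    for rec, prof in analyzed:
        row = {
            "participant_id": rec.participant_id,
            "sex": rec.sex,
            "bmi": rec.bmi,
            "bmi_category": prof.bmi_category,
            "survey_weight": rec.survey_weight,
            "stratum_id": rec.stratum_id,
            "psu_id": rec.psu_id,
            "guideline_met": prof.guideline_met,
            "step_level": prof.step_level,
        }
        for ind in SUMMARY_INDICATORS:
            row[ind] = getattr(prof, ind)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(
    analyzed: Sequence[tuple[ParticipantRecord, ParticipantProfile]],
    *,
    include_underweight: bool = False,
    ci_multiplier: float = 1.96,
    single_psu: str = "collapse",
    adjust_for_wear: bool = False,
    use_design: bool = True,
) -> CohortSummary:
    """Weighted summary grid: indicator x sex x BMI category, plus trends,
    guideline-achievement percentages and step-level distributions.

    Underweight participants are profiled but dropped from the tables by
    default (small-sample convention); empty cells hold NaN, not zero.
    """
    if len(analyzed) == 0:
        raise ValueError("empty analyzed set")
    df = _analysis_frame(analyzed)
    categories = [c for c in BMI_CATEGORIES if include_underweight or c != "underweight"]
    df = df[df["bmi_category"].isin(categories)].reset_index(drop=True)
    sexes = ["all", "male", "female"]

    def cell(frame: pd.DataFrame, col: str) -> tuple[float, float, int]:
        sub = frame.dropna(subset=[col])
        if len(sub) == 0:
            return math.nan, math.nan, 0
        strata = sub["stratum_id"] if use_design else None
        psus = sub["psu_id"] if use_design else None
        try:
            m, se = weighted_mean_se(
                sub[col], sub["survey_weight"], strata, psus, single_psu=single_psu
            )
        except ValueError:
            m = float(
                (sub[col] * sub["survey_weight"]).sum() / sub["survey_weight"].sum()
            )
            se = math.nan
        return m, se, len(sub)

    mean_rows, trend_rows, step_rows, guideline_rows = [], [], [], []
    code_of = {c: i for i, c in enumerate(c for c in BMI_CATEGORIES if c != "underweight")}
    for sex in sexes:
        sdf = df if sex == "all" else df[df["sex"] == sex]
        for indicator in SUMMARY_INDICATORS:
            for cat in categories:
                cdf = sdf[sdf["bmi_category"] == cat]
                m, se, n = cell(cdf, indicator)
                mean_rows.append(
                    {
                        "indicator": indicator,
                        "sex": sex,
                        "bmi_category": cat,
                        "mean": m,
                        "se": se,
                        "ci_low": m - ci_multiplier * se,
                        "ci_high": m + ci_multiplier * se,
                        "n": n,
                    }
                )
            tdf = sdf[sdf["bmi_category"].isin(code_of)].dropna(subset=[indicator])
            if tdf["bmi_category"].nunique() >= 2:
                res = trend_test(
                    tdf[indicator],
                    tdf["survey_weight"],
                    tdf["bmi_category"].map(code_of),
                    covariates=(
                        tdf[["mean_wear_minutes"]].rename(
                            columns={"mean_wear_minutes": "wear"}
                        )
                        if adjust_for_wear and indicator != "mean_wear_minutes"
                        else None
                    ),
                    psus=(tdf["stratum_id"].astype(str) + "/" + tdf["psu_id"].astype(str))
                    if use_design
                    else None,
                )
                trend_rows.append(
                    {
                        "indicator": indicator,
                        "sex": sex,
                        "slope": res.slope,
                        "se": res.se,
                        "p_value": res.p_value,
                        "adjusted_for_wear": res.adjusted_for_wear,
                    }
                )
        for cat in categories:
            cdf = sdf[sdf["bmi_category"] == cat]
            m, se, n = cell(cdf.assign(_g=cdf["guideline_met"].astype(float)), "_g")
            guideline_rows.append(
                {
                    "sex": sex,
                    "bmi_category": cat,
                    "pct_meeting_guideline": m * 100 if not math.isnan(m) else m,
                    "se_pct": se * 100 if not math.isnan(se) else se,
                    "n": n,
                }
            )
            for level in STEP_LEVELS:
                ind = (cdf["step_level"] == level).astype(float)
                m, se, n = cell(cdf.assign(_s=ind), "_s")
                step_rows.append(
                    {
                        "sex": sex,
                        "bmi_category": cat,
                        "step_level": level,
                        "pct": m * 100 if not math.isnan(m) else m,
                        "se_pct": se * 100 if not math.isnan(se) else se,
                        "n": n,
                    }
                )

    return CohortSummary(
        means=pd.DataFrame(mean_rows),
        trends=pd.DataFrame(trend_rows),
        step_levels=pd.DataFrame(step_rows),
        guideline=pd.DataFrame(guideline_rows),
        metadata={
            "trend_test": "survey-weighted least squares on ordinal BMI code, "
            "sandwich covariance",
            "ci_multiplier": ci_multiplier,
            "include_underweight": include_underweight,
            "adjust_for_wear": adjust_for_wear,
            "n_analyzed": int(len(df)),
        },
    )
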