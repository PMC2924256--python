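import math

import numpy as np
import pytest

from actiprofile.cohort import (
    InclusionReport,
    apply_inclusion,
    summarize_cohort,
    trend_test,
    weighted_mean_se,
)
from actiprofile.epochs import ParticipantRecord
from actiprofile.participants import ParticipantProfile


def pp(pid, *, censored=6000.0, moderate=20.0, guideline=False,
       step_level="low_active", bmi_cat="normal", wear=700.0):
    return ParticipantProfile(
        participant_id=pid,
        n_days_worn=7,
        n_valid_days=7,
        mean_wear_minutes=wear,
        mean_nonwear_minutes=1440.0 - wear,
        mean_activity_counts=200_000.0,
        mean_steps_uncensored=censored + 3000.0,
        mean_steps_censored=censored,
        mean_minutes_sedentary=wear - 275.0 - moderate,
        mean_minutes_low=150.0,
        mean_minutes_light=120.0,
        mean_minutes_moderate=moderate,
        mean_minutes_vigorous=5.0,
        mean_breaks=85.0,
        mean_mvpa_bout_minutes=10.0,
        mean_counts_per_min=280.0,
        mean_steps_uncensored_per_min=12.0,
        mean_steps_censored_per_min=8.5,
        guideline_met=guideline,
        step_level=step_level,
        bmi_category=bmi_cat,
    )


def rec(pid, *, sex="male", bmi=24.0, weight=1.0, stratum="S1", psu="U1",
        reliable=True, calibrated=True, pregnant=False):
    return ParticipantRecord(
        participant_id=pid, bmi=bmi, sex=sex, age_years=45.0,
        survey_weight=weight, stratum_id=stratum, psu_id=psu,
        reliable_flag=reliable, calibrated_flag=calibrated,
        pregnant_flag=pregnant,
    )


def ten_participant_fixture():
    """One participant per exclusion rule plus five clean ones."""
    pairs = [
        (rec("x-unreliable", reliable=False), pp("x-unreliable")),
        (rec("x-uncalibrated", calibrated=False), pp("x-uncalibrated")),
        (rec("x-pregnant", sex="female", pregnant=True), pp("x-pregnant")),
        (rec("x-bigbmi", bmi=120.0), pp("x-bigbmi")),
        (rec("x-nowear"), None),
    ]
    pairs += [(rec(f"ok{i}"), pp(f"ok{i}")) for i in range(5)]
    return pairs


class TestApplyInclusion:
    def test_clean_cohort_passes_through(self):
        pairs = [(rec(f"p{i}"), pp(f"p{i}")) for i in range(4)]
        analyzed, report = apply_inclusion(pairs)
        assert report.analyzed == 4 == len(analyzed)
        assert report.eligible == 4

    def test_ten_participant_cascade(self):
        analyzed, report = apply_inclusion(ten_participant_fixture())
        assert report == InclusionReport(
            eligible=10,
            excluded_unreliable=1,
            excluded_uncalibrated=1,
            excluded_pregnant=1,
            excluded_bmi_gt_100=1,
            excluded_no_valid_day=1,
            analyzed=5,
        )
        assert {r.participant_id for r, _ in analyzed} == {f"ok{i}" for i in range(5)}

    def test_first_matching_rule_wins(self):
        both = rec("x", reliable=False, pregnant=True, sex="female")
        _, report = apply_inclusion([(both, pp("x"))])
        assert report.excluded_unreliable == 1
        assert report.excluded_pregnant == 0

    def test_report_must_conserve(self):
        with pytest.raises(ValueError, match="conserve"):
            InclusionReport(10, 1, 1, 1, 1, 1, 9)


class TestWeightedMeanSE:
    def test_equal_weights_mean(self):
        m, _ = weighted_mean_se([1, 2, 3], [1, 1, 1])
        assert m == pytest.approx(2.0)

    def test_weighted_mean(self):
        m, _ = weighted_mean_se([0, 4], [1, 3])
        assert m == pytest.approx(3.0)

    def test_srs_reduces_to_classic_se(self, rng):
        # one stratum, each unit its own PSU: SE must equal s/sqrt(n)
        x = rng.normal(10, 2, size=200)
        m, se = weighted_mean_se(x, np.ones(200))
        assert m == pytest.approx(x.mean())
        assert se == pytest.approx(x.std(ddof=1) / math.sqrt(200), rel=1e-9)

    def test_weight_scale_invariance(self, rng):
        x = rng.normal(size=100)
        w = rng.uniform(0.5, 3.0, size=100)
        m1, se1 = weighted_mean_se(x, w)
        m2, se2 = weighted_mean_se(x, w * 1000)
        assert m1 == pytest.approx(m2)
        assert se1 == pytest.approx(se2)

    def test_matches_psu_bootstrap(self, rng):
        # clustered design: 4 strata x 6 PSUs, PSU-level random effects
        n_psu = 6
        strata, psus, x, w = [], [], [], []
        for h in range(4):
            for c in range(n_psu):
                effect = rng.normal(0, 1.0)
                n = 20
                strata += [h] * n
                psus += [f"{h}-{c}"] * n
                x += list(rng.normal(5 + effect, 1.0, size=n))
                w += list(rng.uniform(0.5, 2.0, size=n))
        _, se = weighted_mean_se(x, w, strata, psus)
        # with-replacement PSU bootstrap; the naive resample of n_h clusters
        # underestimates the with-replacement variance by (n_h - 1)/n_h
        df = {"psus": np.array(psus), "x": np.array(x), "w": np.array(w)}
        by_label = {
            lab: (df["x"][df["psus"] == lab], df["w"][df["psus"] == lab])
            for lab in set(psus)
        }
        reps = []
        for _ in range(800):
            xs, ws = [], []
            for h in range(4):
                labels = [f"{h}-{c}" for c in range(n_psu)]
                for pick in rng.choice(labels, size=n_psu):
                    xs.append(by_label[pick][0])
                    ws.append(by_label[pick][1])
            xa, wa = np.concatenate(xs), np.concatenate(ws)
            reps.append((wa * xa).sum() / wa.sum())
        boot_se = np.std(reps, ddof=1) * np.sqrt(n_psu / (n_psu - 1))
        assert se == pytest.approx(boot_se, rel=0.15)

    def test_single_psu_stratum_policy(self):
        with pytest.raises(ValueError, match="single PSU"):
            weighted_mean_se([1, 2, 3], [1, 1, 1], [0, 0, 1], ["a", "b", "c"])
        m, se = weighted_mean_se(
            [1, 2, 3], [1, 1, 1], [0, 1, 2], ["a", "b", "c"], single_psu="collapse"
        )
        assert m == pytest.approx(2.0)
        assert np.isfinite(se)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_se([1, 2], [1, 0])


class TestTrendTest:
    def test_identical_groups_give_zero_slope(self):
        values = [1, 2, 3] * 3
        codes = [0] * 3 + [1] * 3 + [2] * 3
        res = trend_test(values, [1] * 9, codes)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_recovers_injected_monotone_effect(self, rng):
        # 0.3 SD per category step at n = 500 per group
        n = 500
        codes = np.repeat([0, 1, 2], n)
        y = rng.normal(0, 1, size=3 * n) - 0.3 * codes
        w = rng.uniform(0.5, 2.0, size=3 * n)
        res = trend_test(y, w, codes)
        assert res.slope < 0
        assert res.p_value < 0.05

    def test_adjustment_for_independent_covariate_same_conclusion(self, rng):
        n = 400
        codes = np.repeat([0, 1, 2], n)
        wear = rng.normal(700, 60, size=3 * n)  # independent of category
        y = rng.normal(0, 1, size=3 * n) - 0.4 * codes
        w = np.ones(3 * n)
        plain = trend_test(y, w, codes)
        adj = trend_test(y, w, codes, covariates=wear)
        assert (plain.p_value < 0.05) == (adj.p_value < 0.05)
        assert adj.adjusted_for_wear
        assert adj.slope == pytest.approx(plain.slope, abs=0.1)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="2 categories"):
            trend_test([1, 2], [1, 1], [0, 0])

    def test_weight_scale_invariance(self, rng):
        codes = np.repeat([0, 1, 2], 50)
        y = rng.normal(size=150) + 0.2 * codes
        w = rng.uniform(1, 2, size=150)
        a = trend_test(y, w, codes)
        b = trend_test(y, w * 777, codes)
        assert a.slope == pytest.approx(b.slope)
        assert a.p_value == pytest.approx(b.p_value)


class TestSummarizeCohort:
    def test_hand_computed_six_person_fixture(self):
        # normal-weight males with known weighted mean of censored steps
        analyzed = [
            (rec("a", weight=1.0, psu="U1"), pp("a", censored=5000)),
            (rec("b", weight=2.0, psu="U2"), pp("b", censored=6000)),
            (rec("c", weight=1.0, psu="U1", stratum="S2"), pp("c", censored=7000)),
            (rec("d", weight=2.0, psu="U2", stratum="S2"), pp("d", censored=8000)),
            (rec("e", weight=1.0, psu="U1", stratum="S3"), pp("e", censored=9000)),
            (rec("f", weight=2.0, psu="U2", stratum="S3"), pp("f", censored=10000)),
        ]
        summary = summarize_cohort(analyzed)
        row = summary.means.query(
            "indicator == 'mean_steps_censored' and sex == 'male' "
            "and bmi_category == 'normal'"
        ).iloc[0]
        hand = (5000 + 12000 + 7000 + 16000 + 9000 + 20000) / 9.0
        assert row["mean"] == pytest.approx(hand)
        assert row["n"] == 6
        assert row["ci_low"] <= row["mean"] <= row["ci_high"]

    def test_single_sex_cohort_leaves_other_cells_empty(self):
        analyzed = [(rec(f"m{i}"), pp(f"m{i}")) for i in range(3)]
        summary = summarize_cohort(analyzed)
        female = summary.means.query("sex == 'female' and indicator == 'mean_steps_censored'")
        assert female["mean"].isna().all()
        male = summary.means.query(
            "sex == 'male' and bmi_category == 'normal' and indicator == 'mean_steps_censored'"
        )
        assert male["mean"].notna().all()

    def test_step_level_percentages_sum_to_100(self):
        analyzed = [
            (rec(f"p{i}", weight=1 + i), pp(f"p{i}", step_level=lvl))
            for i, lvl in enumerate(["basal", "low_active", "low_active", "active"])
        ]
        summary = summarize_cohort(analyzed)
        cell = summary.step_levels.query("sex == 'all' and bmi_category == 'normal'")
        assert cell["pct"].sum() == pytest.approx(100.0)

    def test_guideline_percentage(self):
        analyzed = [
            (rec("a", weight=1.0), pp("a", guideline=True)),
            (rec("b", weight=3.0), pp("b", guideline=False)),
        ]
        summary = summarize_cohort(analyzed)
        cell = summary.guideline.query("sex == 'all' and bmi_category == 'normal'").iloc[0]
        assert cell["pct_meeting_guideline"] == pytest.approx(25.0)

    def test_underweight_excluded_by_default(self):
        analyzed = [
            (rec("u", bmi=17.0), pp("u", bmi_cat="underweight")),
            (rec("n", bmi=22.0), pp("n", bmi_cat="normal")),
        ]
        summary = summarize_cohort(analyzed)
        assert "underweight" not in set(summary.means["bmi_category"])
        with_uw = summarize_cohort(analyzed, include_underweight=True)
        assert "underweight" in set(with_uw.means["bmi_category"])

    def test_empty_analyzed_set_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])
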