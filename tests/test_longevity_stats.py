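import numpy as np
import pandas as pd
import pytest

import reportlife as rl
from reportlife import icd9
from reportlife.errors import (EmptyStratumError, IntegrityError,
                               ParameterError)
from reportlife.longevity_stats import AGE_GROUPS, STRATIFIERS


class TestReportAge:
    def test_36_hours_is_one_and_a_half_days(self):
        assert rl.report_age("2007-01-02 12:00", "2007-01-01 00:00") == 1.5

    def test_zero_case(self):
        assert rl.report_age("2007-01-01", "2007-01-01") == 0.0

    def test_random_pairs_equal_epoch_arithmetic_oracle(self):
        rng = np.random.default_rng(0)
        t0 = pd.Timestamp("2006-01-01")
        for _ in range(100):
            a = t0 + pd.Timedelta(seconds=int(rng.integers(0, 10**7)))
            b = a + pd.Timedelta(seconds=int(rng.integers(0, 10**7)))
            oracle = (b.value - a.value) / 1e9 / 86400.0
            assert rl.report_age(b, a) == pytest.approx(oracle, abs=1e-12)


class TestMedianLife:
    def test_constant_list(self):
        s = rl.median_life([5, 5, 5])
        assert (s.median_life, s.p25, s.p75) == (5.0, 5.0, 5.0)
        assert s.n_views == 3

    def test_1_to_100_midpoint(self):
        # linear interpolation between closest order statistics
        s = rl.median_life(range(1, 101))
        assert s.median_life == 50.5
        assert s.p25 == np.percentile(np.arange(1, 101), 25)

    def test_empty_raises_explicitly(self):
        with pytest.raises(EmptyStratumError, match="dept-x"):
            rl.median_life([], stratum="dept-x")

    def test_quartile_coherence_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ages = rng.exponential(10, size=int(rng.integers(1, 200)))
            s = rl.median_life(ages)
            assert s.p25 <= s.median_life <= s.p75

    def test_dispersion_ratio(self):
        s = rl.median_life([1, 2, 3, 4, 5])
        assert s.dispersion_ratio == pytest.approx(s.p75 / s.p25)


class TestAssignAgeGroup:
    @pytest.mark.parametrize("age,label", [
        (12, "child"), (13, "teenager"), (19, "teenager"), (20, "young adult"),
        (34, "young adult"), (35, "adult"), (54, "adult"), (55, "old adult"),
        (69, "old adult"), (70, "senior"), (0, "child"), (120, "senior"),
    ])
    def test_bins(self, age, label):
        assert rl.assign_age_group(age) == label

    def test_exhaustive_against_interval_table_oracle(self):
        table = [(lo, (hi if hi is not None else 10**9), lab)
                 for lab, lo, hi in AGE_GROUPS]
        for age in range(0, 121):
            expected = [lab for lo, hi, lab in table if lo <= age <= hi]
            assert len(expected) == 1      # partition: no gaps, no overlap
            assert rl.assign_age_group(age) == expected[0]

    def test_negative_age_rejected(self):
        with pytest.raises(ParameterError):
            rl.assign_age_group(-1)


class TestStratifiedMedianLife:
    def test_single_stratum_equals_plain_median_life(self):
        df = pd.DataFrame({
            "department": ["pathology"] * 7,
            "report_age_days": [1.0, 2, 3, 4, 5, 6, 7],
        })
        out = rl.stratified_median_life(df, "department")
        assert len(out) == 1
        plain = rl.median_life(df["report_age_days"])
        assert out["median_life"].iloc[0] == plain.median_life
        assert out["p25"].iloc[0] == plain.p25

    def test_unknown_stratifier_lists_options(self):
        df = pd.DataFrame({"report_age_days": [1.0]})
        with pytest.raises(ParameterError) as err:
            rl.stratified_median_life(df, "nope")
        for name in STRATIFIERS:
            assert name in str(err.value)

    def test_per_stratum_counts_sum_to_total(self, classified):
        out = rl.stratified_median_life(classified, "creation_encounter_type")
        assert out["n_views"].sum() == len(classified)

    def test_icd9_strata_restricted_to_inpatient_reports(self, classified):
        out = rl.stratified_median_life(classified, "icd9_chapter")
        n_inpat = ((classified["producing_encounter_type"] == "inpatient")
                   & classified["main_dx"].notna()).sum()
        assert out["n_views"].sum() == n_inpat

    def test_icd9_section_suppresses_small_strata(self):
        ages = list(np.linspace(1, 10, 21)) + [3.0] * 20
        df = pd.DataFrame({
            "producing_encounter_type": ["inpatient"] * 41,
            "main_dx": ["486"] * 21 + ["410.91"] * 20,
            "report_age_days": ages,
        })
        out = rl.stratified_median_life(df, "icd9_section")
        # 21 views survive (> 20), 20 views suppressed (<= 20)
        assert list(out["stratum"]) == ["Pneumonia and influenza"]

    def test_sex_and_age_group_strata(self, classified):
        by_sex = rl.stratified_median_life(classified, "sex")
        assert set(by_sex["stratum"]) <= {"F", "M"}
        by_age = rl.stratified_median_life(classified, "age_group")
        assert set(by_age["stratum"]) <= {lab for lab, *_ in AGE_GROUPS}

    def test_percentile_coherence_all_emitted(self, classified):
        for strat in ("department", "creation_encounter_type", "age_group"):
            out = rl.stratified_median_life(classified, strat)
            assert (out["p25"] <= out["median_life"]).all()
            assert (out["median_life"] <= out["p75"]).all()
            assert (out["n_views"] >= 1).all()


class TestUsageEvolution:
    def _fixture(self):
        sessions = pd.DataFrame({
            "session_id": ["S1"],
            "login": ["u1"],
            "ip": ["10.0.0.1"],
            "start": ["2007-10-05 10:00"],
            "user_category": ["physician"],
            "is_dev": [False],
        })
        views = pd.DataFrame({
            "view_id": ["V1"], "session_id": ["S1"], "report_id": ["R1"],
            "request_time": ["2007-10-05 10:01"],
        })
        encounters = pd.DataFrame({
            "encounter_id": [f"E{i}" for i in range(10_000)],
            "patient_id": ["P1"] * 10_000,
            "type": ["outpatient"] * 10_000,
            "start": ["2007-11-01"] * 10_000,
            "end": ["2007-11-01"] * 10_000,
            "main_dx": [""] * 10_000,
        })
        return sessions, views, encounters

    def test_per_10k_formula_unit_case(self):
        sessions, views, encounters = self._fixture()
        out = rl.usage_evolution(sessions, views, encounters).set_index("period")
        row = out.loc["2007Q4"]
        assert row["sessions"] == 1
        assert row["views"] == 1
        assert row["distinct_users"] == 1
        assert row["encounters"] == 10_000
        # (views / users) / encounters * 10,000 = 1
        assert row["views_per_user_per_10k_encounters"] == 1.0

    def test_zero_user_period_emits_null(self):
        sessions, views, encounters = self._fixture()
        out = rl.usage_evolution(sessions.iloc[0:0], views.iloc[0:0],
                                 encounters).set_index("period")
        assert np.isnan(out.loc["2007Q4", "views_per_user"])

    def test_distinct_counts_equal_set_oracle(self, small_cohort):
        c = small_cohort
        out = rl.usage_evolution(c.sessions, c.views, c.encounters)
        sess = c.sessions.copy()
        sess["q"] = pd.to_datetime(sess["start"]).dt.to_period("Q").astype(str)
        for _, row in out.iterrows():
            grp = sess.loc[sess["q"] == row["period"]]
            assert row["distinct_users"] == len(set(grp["login"]))
            assert row["distinct_computers"] == len(set(grp["ip"]))
            assert row["sessions"] == len(set(grp["session_id"]))


class TestCreationViewCrosstab:
    def test_diagonal_only_means_zero_previous(self):
        df = pd.DataFrame({
            "age_anchor": ["2007-10-01", "2007-11-05"],
            "request_time": ["2007-10-02", "2007-12-01"],
        })
        mat, prev = rl.creation_view_crosstab(df)
        assert (prev.dropna() == 0.0).all()

    def test_marginal_sums_oracle(self, classified):
        mat, prev = rl.creation_view_crosstab(classified)
        assert mat.to_numpy().sum() == len(classified)
        vq = pd.to_datetime(classified["request_time"]).dt.to_period(
            "Q").astype(str)
        for q, n in vq.value_counts().items():
            assert mat[q].sum() == n

    def test_upper_triangular_structure(self, classified):
        mat, _ = rl.creation_view_crosstab(classified)
        arr = mat.to_numpy()
        below = np.tril(arr, k=-1)
        assert below.sum() == 0  # no views before creation

    def test_view_before_creation_is_integrity_error(self):
        df = pd.DataFrame({"age_anchor": ["2007-10-01"],
                           "request_time": ["2007-09-01"]})
        with pytest.raises(IntegrityError):
            rl.creation_view_crosstab(df)

    def test_previous_quarter_pct_hand_case(self):
        # view quarter Q2: 3 views of Q2 reports, 1 view of a Q1 report
        df = pd.DataFrame({
            "age_anchor": ["2007-04-02"] * 3 + ["2007-02-01"],
            "request_time": ["2007-05-01"] * 4,
        })
        _, prev = rl.creation_view_crosstab(df)
        assert prev["2007Q2"] == pytest.approx(25.0)


class TestAgingCurve:
    def test_p50_equals_median_life(self, classified):
        curves = rl.aging_curve(classified)
        table = rl.stratified_median_life(classified,
                                          "creation_encounter_type")
        med = table.set_index("stratum")["median_life"]
        for key, curve in curves.items():
            p50 = curve.loc[curve["percentile"] == 50, "age_days"].iloc[0]
            assert p50 == pytest.approx(med[key])

    def test_constant_ages_step_function(self):
        df = pd.DataFrame({"producing_encounter_type": ["emergency"] * 10,
                           "report_age_days": [4.0] * 10})
        curve = rl.aging_curve(df)["emergency"]
        assert (curve["age_days"] == 4.0).all()

    def test_monotone_nondecreasing_in_percentile(self, classified):
        for curve in rl.aging_curve(classified).values():
            assert (np.diff(curve["age_days"]) >= -1e-12).all()

    def test_smaller_decay_rate_dominates(self):
        slow = rl.generate_view_ages(5000, 0.6, 0.05, seed=1) * rl.DAYS_PER_MONTH
        fast = rl.generate_view_ages(5000, 0.6, 0.5, seed=2) * rl.DAYS_PER_MONTH
        df = pd.DataFrame({
            "producing_encounter_type": ["outpatient"] * 5000
            + ["emergency"] * 5000,
            "report_age_days": np.concatenate([slow, fast]),
        })
        curves = rl.aging_curve(df)
        o = curves["outpatient"].set_index("percentile")["age_days"]
        e = curves["emergency"].set_index("percentile")["age_days"]
        assert (o.loc[50:95] >= e.loc[50:95]).all()


class TestIcd9:
    def test_chapter_examples(self):
        assert icd9.chapter_of("162.9") == "Neoplasms"
        assert icd9.chapter_of("821.01") == "Injury and poisoning"
        assert "Supplementary" in icd9.chapter_of("V30.00")
        assert "external causes" in icd9.chapter_of("E880.9")

    def test_section_examples(self):
        assert icd9.section_of("233.1") == "Carcinoma in situ"
        assert icd9.section_of("904.2") == "Injury to blood vessels"
        assert icd9.section_of("204.00") == (
            "Malignant neoplasm of lymphatic and haematopoietic tissue")

    def test_chapter_totality_range_scan_oracle(self):
        def oracle(prefix, num):
            hits = [lab for p, lo, hi, lab in icd9.CHAPTERS
                    if p == prefix and lo <= num <= hi]
            return hits

        for num in range(1, 1000):
            assert len(oracle("N", num)) == 1
            assert icd9.chapter_of(f"{num:03d}") == oracle("N", num)[0]
        for num in range(1, 92):
            assert len(oracle("V", num)) == 1
        for num in range(0, 1000):
            assert len(oracle("E", num)) == 1

    def test_sections_nest_inside_one_chapter(self):
        for prefix, lo, hi, label in icd9.SECTIONS:
            ch_lo = icd9._scan(icd9.CHAPTERS, prefix, lo)
            ch_hi = icd9._scan(icd9.CHAPTERS, prefix, hi)
            assert ch_lo is not None and ch_lo == ch_hi, label

    def test_sections_do_not_overlap(self):
        seen = {}
        for prefix, lo, hi, label in icd9.SECTIONS:
            for num in range(lo, hi + 1):
                assert (prefix, num) not in seen, (label, seen.get((prefix, num)))
                seen[(prefix, num)] = label

    def test_invalid_codes_rejected(self):
        for bad in ("", "X12", "12345", "V99", "000"):
            with pytest.raises(ParameterError):
                icd9.parse_rubric(bad)
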