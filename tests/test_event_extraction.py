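import numpy as np
import pandas as pd
import pytest

from underdx.event_extraction import (DataError, DeathDefinition,
                                      classify_death, filter_eligible,
                                      tabulate_strata, COUNT_COLUMNS)
from underdx.strata import KEY_COLUMNS

COND = "gout"
HAND_YEARS = [2015, 2016]


class TestEligibility:
    def _frame(self, **kw):
        row = dict(person_id=0, sex="female", birth_date="1970-01-01",
                   qimd=3, region="London", registration_start="2000-01-01",
                   registration_end="2016-12-31")
        row.update(kw)
        f = pd.DataFrame([row])
        for c in ("birth_date", "registration_start", "registration_end"):
            f[c] = pd.to_datetime(f[c])
        return f

    def test_six_month_registration_excluded(self):
        f = self._frame(registration_start="2015-01-01",
                        registration_end="2015-07-01")
        assert filter_eligible(f, "2015-01-01", "2016-12-31").empty

    def test_person_under_30_throughout_excluded(self):
        f = self._frame(birth_date="1995-06-01")
        assert filter_eligible(f, "2015-01-01", "2016-12-31").empty

    def test_censor_before_registration_excluded(self):
        f = self._frame(registration_start="2012-01-01",
                        registration_end="2011-06-30")
        kept, log = filter_eligible(f, "2015-01-01", "2016-12-31",
                                    return_log=True)
        assert kept.empty
        assert "censor" in log["reason"].iloc[0]

    def test_missing_demographics_rejected_with_reason(self):
        f = self._frame(sex=None)
        kept, log = filter_eligible(f, "2015-01-01", "2016-12-31",
                                    return_log=True)
        assert kept.empty
        assert "missing" in log["reason"].iloc[0]

    def test_hand_cohort_keeps_ten_of_twelve(self, hand_cohort):
        persons, _, _ = hand_cohort
        kept, log = filter_eligible(persons, "2015-01-01", "2016-12-31",
                                    return_log=True)
        assert sorted(kept["person_id"]) == [1, 2, 3, 4, 5, 7, 8, 9, 11, 12]
        assert sorted(log["person_id"]) == [6, 10]


class TestClassifyDeath:
    CAUSES_CONTRIB = [("other", "primary"), (COND, "contributing")]
    CAUSES_PRIMARY = [(COND, "primary")]

    def test_contributing_cause_without_diagnosis_is_undiagnosed(self):
        got = classify_death("2016-03-01", self.CAUSES_CONTRIB, [], COND)
        assert got == "undiagnosed_death"

    def test_contributing_cause_not_undiagnosed_under_primary_only(self):
        got = classify_death("2016-03-01", self.CAUSES_CONTRIB, [], COND,
                             DeathDefinition.PRIMARY_CAUSE_ONLY)
        assert got == "other_cause"

    def test_recent_diagnosis_flips_under_expanded_definition(self):
        dx = ["2015-09-03"]  # 180 days before death
        assert classify_death("2016-03-01", self.CAUSES_PRIMARY, dx, COND,
                              "main") == "diagnosed_death"
        assert classify_death("2016-03-01", self.CAUSES_PRIMARY, dx, COND,
                              "expanded_last_year") == "undiagnosed_death"

    def test_old_diagnosis_stays_diagnosed_under_expanded(self):
        got = classify_death("2016-03-01", self.CAUSES_PRIMARY,
                             ["2013-01-01"], COND, "expanded_last_year")
        assert got == "diagnosed_death"

    def test_unrelated_cause_is_other(self):
        got = classify_death("2016-03-01", [("other", "primary")],
                             ["2013-01-01"], COND)
        assert got == "other_cause"

    def test_diagnosis_after_death_is_a_data_error(self):
        with pytest.raises(DataError):
            classify_death("2016-03-01", self.CAUSES_PRIMARY,
                           ["2016-05-01"], COND)


class TestHandTabulation:
    def test_counts_match_manual_enumeration_exactly(self, hand_cohort,
                                                     hand_expected_counts):
        persons, dx, deaths = hand_cohort
        eligible = filter_eligible(persons, "2015-01-01", "2016-12-31")
        counts = tabulate_strata(eligible, dx, deaths, COND, years=HAND_YEARS)
        assert len(counts) == 900  # 450 strata x 2 years, zero-filled
        nonzero = counts[counts[COUNT_COLUMNS].any(axis=1)]
        merged = hand_expected_counts.merge(
            nonzero, on=KEY_COLUMNS, how="outer", suffixes=("_exp", ""),
            indicator=True)
        assert (merged["_merge"] == "both").all(), merged
        for c in COUNT_COLUMNS:
            assert (merged[f"{c}_exp"] == merged[c]).all(), c

    def test_primary_only_drops_contributing_cause_death(self, hand_cohort):
        persons, dx, deaths = hand_cohort
        eligible = filter_eligible(persons, "2015-01-01", "2016-12-31")
        main = tabulate_strata(eligible, dx, deaths, COND, years=HAND_YEARS)
        strict = tabulate_strata(eligible, dx, deaths, COND,
                                 definition="primary_cause_only",
                                 years=HAND_YEARS)
        # P4's contributing-cause death no longer counts as undiagnosed
        assert main["Z_U"].sum() == 2
        assert strict["Z_U"].sum() == 1
        assert strict["Z_0"].sum() == main["Z_0"].sum() + 1

    def test_expanded_definition_reclassifies_recent_diagnosis(self,
                                                               hand_cohort):
        persons, dx, deaths = hand_cohort
        eligible = filter_eligible(persons, "2015-01-01", "2016-12-31")
        exp = tabulate_strata(eligible, dx, deaths, COND,
                              definition="expanded_last_year",
                              years=HAND_YEARS)
        # P5 (died 250 days after diagnosis) moves from Z_D to Z_U
        assert exp["Z_U"].sum() == 3
        assert exp["Z_D"].sum() == 1

    def test_concentration_rule_delays_diagnosis_date(self, hand_cohort):
        persons, dx, deaths = hand_cohort
        eligible = filter_eligible(persons, "2015-01-01", "2016-12-31")
        counts = tabulate_strata(eligible, dx, deaths, COND, years=HAND_YEARS,
                                 min_event_count=2)
        # only P12 has two events; her qualifying date moves to 2016
        assert counts["incident_diagnoses"].sum() == 1
        row = counts[(counts["incident_diagnoses"] > 0)]
        assert row["year"].iloc[0] == 2016


class TestSimulatedTabulation:
    def test_reproduces_truth_table_exactly(self, small_sim):
        params, persons, dx, deaths, truth = small_sim
        eligible = filter_eligible(persons, "2008-01-01", "2012-12-31")
        assert len(eligible) == len(persons)
        for cond in params.conditions:
            counts = tabulate_strata(eligible, dx, deaths, cond,
                                     years=range(2008, 2013))
            m = truth[truth["condition"] == cond].merge(
                counts, on=KEY_COLUMNS, suffixes=("_t", ""))
            assert len(m) == 450 * 5
            for col in ("Z_U", "Z_D", "Z_0", "Y", "person_years"):
                assert (m[f"{col}_t"] == m[col]).all(), (cond, col)

    def test_definition_monotonicity_holds_stratum_wise(self, small_sim):
        params, persons, dx, deaths, _ = small_sim
        eligible = filter_eligible(persons, "2008-01-01", "2012-12-31")
        cond = "lung_cancer"
        z = {}
        for d in ("primary_cause_only", "main", "expanded_last_year"):
            z[d] = tabulate_strata(eligible, dx, deaths, cond, definition=d,
                                   years=range(2008, 2013))["Z_U"].to_numpy()
        assert (z["primary_cause_only"] <= z["main"]).all()
        assert (z["main"] <= z["expanded_last_year"]).all()
        assert z["primary_cause_only"].sum() < z["main"].sum()
        assert z["main"].sum() < z["expanded_last_year"].sum()

    def test_every_year_has_450_strata(self, small_sim):
        params, persons, dx, deaths, _ = small_sim
        eligible = filter_eligible(persons, "2008-01-01", "2012-12-31")
        counts = tabulate_strata(eligible, dx, deaths, "hypertension",
                                 years=range(2008, 2013))
        sizes = counts.groupby("year").size()
        assert (sizes == 450).all()
        assert not counts.duplicated(KEY_COLUMNS).any()
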