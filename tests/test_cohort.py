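"""Case definition, inclusion/exclusion rules, censoring, and splitting."""

import numpy as np
import pandas as pd
import pytest

from riskpipe import cohort, pipeline
from riskpipe.cohort import CaseDefinition
from riskpipe.synthetic import EPOCH, SimConfig, generate_cohort

from conftest import make_demographics, make_events


def day(d: int) -> pd.Timestamp:
    return EPOCH + pd.Timedelta(days=d)


class TestFindCases:
    def test_prefix_match_sets_case_and_date(self):
        ev = make_events(("A", 5, "DX", "340"), ("A", 200, "DX", "E950.0"))
        labels = cohort.find_cases(ev)
        row = labels.set_index("patient_id").loc["A"]
        assert row["is_case"]
        assert row["first_event_date"] == day(200)
        assert row["first_marker_date"] == day(5)

    def test_dot_stripped_dialects_match_same_prefix(self):
        """'9650' and '965.0' both match the prefix 965 after normalization."""
        ev = make_events(("A", 1, "DX", "9650"), ("B", 1, "DX", "965.0"))
        labels = cohort.find_cases(ev)
        assert labels["is_case"].all()

    def test_non_dx_codes_never_define_cases(self):
        ev = make_events(("A", 1, "RX", "9650"), ("A", 2, "LAB", "E9500", "H"))
        labels = cohort.find_cases(ev)
        assert not labels["is_case"].any()

    def test_external_case_date_participates_in_minimum(self):
        ev = make_events(("A", 300, "DX", "E9500"))
        cd = CaseDefinition(external_cases={"A": day(100), "B": day(50)})
        labels = cohort.find_cases(ev, cd).set_index("patient_id")
        assert labels.loc["A", "first_event_date"] == day(100)
        assert labels.loc["B", "is_case"]
        assert labels.loc["B", "first_event_date"] == day(50)

    def test_empty_prefixes_rejected(self):
        with pytest.raises(ValueError):
            CaseDefinition(code_prefixes=())


class TestInclusion:
    def _labels(self, ev, demo):
        return cohort.apply_inclusion(ev, demo, cohort.find_cases(ev))

    def test_three_visits_31_days_included(self):
        ev = make_events(("A", 0, "DX", "1"), ("A", 10, "DX", "2"), ("A", 31, "DX", "3"))
        labels = self._labels(ev, make_demographics(["A"], birth_year=1960))
        assert labels.set_index("patient_id").loc["A", "included"]

    def test_single_date_excluded_too_few_visits(self):
        ev = make_events(*[("A", 5, "DX", str(i)) for i in range(5)])
        row = self._labels(ev, make_demographics(["A"])).set_index("patient_id").loc["A"]
        assert not row["included"] and row["exclusion_reason"] == "too_few_visits"

    def test_29_day_span_excluded_30_inclusive(self):
        ev = make_events(("A", 0, "DX", "1"), ("A", 10, "DX", "2"), ("A", 29, "DX", "3"))
        row = self._labels(ev, make_demographics(["A"])).set_index("patient_id").loc["A"]
        assert row["exclusion_reason"] == "span_too_short"
        ev30 = make_events(("A", 0, "DX", "1"), ("A", 10, "DX", "2"), ("A", 30, "DX", "3"))
        assert self._labels(ev30, make_demographics(["A"]))["included"].all()

    def test_missing_birth_year_fails_closed(self):
        ev = make_events(("A", 0, "DX", "1"), ("A", 10, "DX", "2"), ("A", 40, "DX", "3"))
        demo = make_demographics(["A"])
        demo["birth_year"] = np.nan
        row = self._labels(ev, demo).set_index("patient_id").loc["A"]
        assert row["exclusion_reason"] == "age_out_of_range"

    def test_age_outside_10_90_excluded(self):
        ev = make_events(("A", 0, "DX", "1"), ("A", 10, "DX", "2"), ("A", 40, "DX", "3"))
        row = (
            self._labels(ev, make_demographics(["A"], birth_year=1905))
            .set_index("patient_id").loc["A"]
        )
        assert row["exclusion_reason"] == "age_out_of_range"


class TestCaseExclusions:
    def _run(self, ev):
        labels = cohort.apply_inclusion(ev, make_demographics(sorted(ev["patient_id"].unique())), cohort.find_cases(ev))
        return cohort.apply_case_exclusions(ev, labels).set_index("patient_id")

    def test_no_events_before_event_date_excluded(self):
        ev = make_events(
            ("A", 50, "DX", "E9500"), ("A", 50, "DX", "111"),
            ("A", 60, "DX", "222"), ("A", 90, "DX", "333"),
        )
        row = self._run(ev).loc["A"]
        assert row["exclusion_reason"] == "no_prior_data"

    def test_event_before_marker_excluded(self):
        ev = make_events(
            ("A", 10, "DX", "000"), ("A", 50, "DX", "E9500"),
            ("A", 100, "DX", "340"), ("A", 45, "DX", "123"),
        )
        row = self._run(ev).loc["A"]
        assert row["exclusion_reason"] == "event_before_marker"

    def test_same_day_marker_and_event_retained(self):
        ev = make_events(
            ("A", 10, "DX", "000"), ("A", 100, "DX", "340"),
            ("A", 100, "DX", "E9500"), ("A", 60, "DX", "123"),
        )
        row = self._run(ev).loc["A"]
        assert row["included"] and row["exclusion_reason"] == "none"

    def test_caseless_marker_patient_untouched(self):
        ev = make_events(("A", 0, "DX", "340"), ("A", 20, "DX", "1"), ("A", 40, "DX", "2"))
        assert self._run(ev).loc["A", "included"]


class TestCensoring:
    def test_strictly_before_rule(self):
        ev = make_events(
            ("A", 10, "DX", "000"), ("A", 50, "DX", "111"),
            ("A", 50, "DX", "E9500"), ("A", 60, "DX", "222"),
        )
        labels = cohort.find_cases(ev)
        out = cohort.censor_case_records(ev, labels)
        assert list(out["date"]) == [day(10)]

    def test_controls_pass_through(self):
        ev = make_events(("A", 10, "DX", "000"), ("A", 50, "RX", "111"))
        labels = cohort.find_cases(ev)
        pd.testing.assert_frame_equal(cohort.censor_case_records(ev, labels), ev)

    def test_idempotent(self, small_cohort):
        labels = pipeline.build_labels(small_cohort.events, small_cohort.demographics)
        once = cohort.censor_case_records(small_cohort.events, labels)
        twice = cohort.censor_case_records(once, labels)
        pd.testing.assert_frame_equal(once, twice)


class TestTemporalOrder:
    def test_counts_are_mutually_exclusive(self):
        labels = pd.DataFrame(
            {
                "patient_id": ["A", "B", "C", "D"],
                "is_case": [True, True, True, False],
                "first_event_date": [day(10), day(5), day(7), pd.NaT],
                "first_marker_date": [day(3), day(9), day(7), pd.NaT],
            }
        )
        assert cohort.classify_temporal_order(labels) == {
            "marker_first": 1, "event_first": 1, "same_day": 1,
        }

    def test_zero_cases(self):
        labels = pd.DataFrame(
            {"patient_id": [], "is_case": [], "first_event_date": [],
             "first_marker_date": []}
        )
        counts = cohort.classify_temporal_order(labels)
        assert sum(counts.values()) == 0


class TestSplit:
    def _labels(self, n):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "is_case": [i < max(1, n // 10) for i in range(n)],
                "first_event_date": pd.NaT,
                "first_marker_date": pd.NaT,
                "included": True,
                "exclusion_reason": "none",
            }
        )

    @pytest.mark.parametrize("n,sizes", [(10, {5}), (11, {5, 6})])
    def test_halves_differ_by_at_most_one(self, n, sizes):
        out = cohort.split_train_test(self._labels(n), split_seed=3)
        counts = out["arm"].value_counts()
        assert set(counts.to_list()) == sizes

    def test_partition_and_determinism(self):
        labels = self._labels(101)
        a = cohort.split_train_test(labels, split_seed=9)
        b = cohort.split_train_test(labels, split_seed=9)
        assert a["arm"].notna().all()
        pd.testing.assert_series_equal(a["arm"], b["arm"])
        assert (cohort.split_train_test(labels, split_seed=10)["arm"] != a["arm"]).any()

    def test_stratified_split_balances_cases(self):
        labels = self._labels(100)  # 10 cases
        out = cohort.split_train_test(labels, split_seed=1, stratify=True)
        by_arm = out.groupby("arm")["is_case"].sum()
        assert set(by_arm.to_list()) == {5}

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            cohort.split_train_test(self._labels(1), split_seed=0)


class TestDemographicsSummary:
    def test_sex_ratio_value(self):
        assert round(cohort.sex_ratio(11072, 4043), 1) == 2.7

    def test_one_sex_gives_inf_sentinel(self):
        assert cohort.sex_ratio(5, 0) == float("inf")

    def test_empty_cohort_gives_empty_summary(self):
        out = cohort.summarize_demographics(pd.DataFrame(), pd.DataFrame())
        assert out.table.empty and out.sex_ratio == {}

    def test_percentages_and_groups(self):
        demo = make_demographics(["A", "B", "C", "D"])
        demo.loc[demo["patient_id"].isin(["C", "D"]), "sex"] = "M"
        labels = pd.DataFrame(
            {"patient_id": ["A", "B", "C", "D"], "is_case": [True, False, False, False]}
        )
        out = cohort.summarize_demographics(labels, demo)
        sexrow = out.table[(out.table["feature"] == "sex") & (out.table["category"] == "F")]
        assert sexrow["n_all"].iloc[0] == 2 and sexrow["pct_all"].iloc[0] == 50.0
        assert out.sex_ratio["all"] == 1.0
        assert out.sex_ratio["cases"] == float("inf")


class TestAccounting:
    def test_identified_equals_included_plus_exclusions(self):
        """Generated with both exclusion toggles on, the case bookkeeping adds
        up: identified = included + per-reason exclusions, with both
        case-specific reasons realized."""
        cfg = SimConfig(
            n_patients=4_000, subpop_fraction=1.0, baseline_prevalence=0.02,
            no_history_case_frac=0.2, marker_after_event_frac=0.3,
            n_noise_codes=40, events_per_year=4.0, seed=13,
        )
        res = generate_cohort(cfg)
        labels = pipeline.build_labels(res.events, res.demographics)
        acc = cohort.exclusion_accounting(labels)
        reasons = [k for k in acc if k not in ("cases_identified", "cases_included")]
        assert acc["cases_identified"] == acc["cases_included"] + sum(
            acc[r] for r in reasons
        )
        assert acc["no_prior_data"] > 0
        assert acc["event_before_marker"] > 0
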