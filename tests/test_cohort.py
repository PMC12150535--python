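"""Eligibility, exclusion cascade and timeline alignment."""

import numpy as np
import pandas as pd
import pytest

from diatraj._errors import ConfigurationError, ContractError, DomainError
from diatraj.cohort import (
    ExclusionLog,
    align_timeline,
    align_timeline_from_truth,
    apply_exclusions,
    ascertain_t2d,
    has_fhd,
    select_controls,
    select_incident_cases,
)
from diatraj.simulate import SimulationConfig, simulate_cohort


def _participants(rows):
    base = {
        "group": "MARD", "sex": "female", "fhd": "no", "gada_positive": False,
        "baseline_age": 45.0, "diagnosis_time": np.nan,
        "diagnosed_via_registry": False, "classification_exam": 0,
        "exams_attended": "1|2|3",
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def _exams(rows):
    base = {
        "exam_time": 0.0, "age": 45.0, "fpg": 85.0, "glucose_2h": 80.0,
        "fasting_insulin": 10.0, "bmi": 25.0, "whr": 0.85, "sbp": 120.0,
        "dbp": 75.0, "smoking": "never", "education": "white_collar_lower",
        "physical_activity": "light", "bp_medication": False,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def _full_attendance_exams(pids, **overrides):
    rows = []
    for pid in pids:
        for e, t in ((1, 0.0), (2, 10.0), (3, 20.0)):
            rows.append({"participant_id": pid, "exam_index": e, "exam_time": t,
                         **overrides.get(pid, {})})
    return _exams(rows)


class TestAscertainment:
    @pytest.mark.parametrize(
        "fpg,g2h,reg,expected",
        [
            (126.0, np.nan, False, True),     # fasting threshold is inclusive
            (125.9, 199.9, False, False),     # both just below
            (100.0, np.nan, True, True),      # registry flag dominates
            (100.0, 200.0, False, True),      # post-load threshold inclusive
            (np.nan, 150.0, None, False),
        ],
    )
    def test_ogtt_and_registry_rules(self, fpg, g2h, reg, expected):
        assert ascertain_t2d(fpg, g2h, reg) is expected

    def test_all_missing_rejected(self):
        with pytest.raises(ContractError):
            ascertain_t2d(np.nan, np.nan, None)

    @pytest.mark.parametrize(
        "first,second,expected",
        [(1, 0, True), (0, 1, False), (0, 2, True), (0, 0, False), (2, 0, True)],
    )
    def test_family_history_rule(self, first, second, expected):
        assert has_fhd(first, second) is expected

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            has_fhd(-1, 0)


class TestIncidentCaseSelection:
    def test_within_window_classified_at_earliest_exam(self):
        p = _participants([{"participant_id": "A", "diagnosis_time": 8.0}])
        e = _full_attendance_exams(["A"])
        cases, log = select_incident_cases(p, e)
        assert list(cases["classification_exam"]) == [2]
        assert cases["diagnosis_to_exam_years"].iloc[0] == pytest.approx(2.0)
        assert log.total_removed == 0

    def test_stale_diagnosis_excluded_under_5y_rule(self):
        # diagnosed 6 years before exam 2, exam 3 not attended
        p = _participants([{"participant_id": "A", "diagnosis_time": 4.0}])
        e = _exams([
            {"participant_id": "A", "exam_index": 1, "exam_time": 0.0},
            {"participant_id": "A", "exam_index": 2, "exam_time": 10.0},
        ])
        cases, log = select_incident_cases(p, e)
        assert len(cases) == 0
        assert log.entries[0][0] == "no_exam_within_5y_of_diagnosis"

    def test_post_classification_exam_retained(self):
        p = _participants([{"participant_id": "A", "diagnosis_time": 9.0}])
        e = _full_attendance_exams(["A"])
        cases, _ = select_incident_cases(p, e)
        assert cases["classification_exam"].iloc[0] == 2  # exam 3 stays as post data

    def test_diagnosis_at_baseline_excluded(self):
        p = _participants([{"participant_id": "A", "diagnosis_time": 0.0}])
        e = _full_attendance_exams(["A"])
        cases, log = select_incident_cases(p, e)
        assert len(cases) == 0
        assert log.entries[0][0] == "diagnosis_not_after_baseline"

    def test_diagnosis_after_last_attended_exam_excluded(self):
        p = _participants([{"participant_id": "A", "diagnosis_time": 12.0}])
        e = _exams([
            {"participant_id": "A", "exam_index": 1, "exam_time": 0.0},
            {"participant_id": "A", "exam_index": 2, "exam_time": 10.0},
        ])
        cases, log = select_incident_cases(p, e)
        assert len(cases) == 0 and log.total_removed == 1


class TestControlSelection:
    def test_threshold_crossing_disqualifies(self):
        p = _participants([{"participant_id": c} for c in "AB"])
        e = _full_attendance_exams(["A", "B"])
        e.loc[(e["participant_id"] == "B") & (e["exam_index"] == 3), "fpg"] = 130.0
        controls = select_controls(p, e)
        assert list(controls["participant_id"]) == ["A"]

    def test_fhd_toggle_semantics(self):
        p = _participants([
            {"participant_id": "A", "fhd": "yes"},
            {"participant_id": "B", "fhd": "no"},
        ])
        e = _full_attendance_exams(["A", "B"])
        keep = select_controls(p, e, exclude_fhd=False)
        assert set(keep["participant_id"]) == {"A", "B"}
        strict = select_controls(p, e, exclude_fhd=True)
        assert set(strict["participant_id"]) == {"B"}
        # the FHD-excluded control set is a subset of the default set
        assert set(strict["participant_id"]) <= set(keep["participant_id"])

    def test_registry_flag_disqualifies(self):
        p = _participants([{"participant_id": "A", "diagnosed_via_registry": True}])
        e = _full_attendance_exams(["A"])
        assert len(select_controls(p, e)) == 0


def _toy_exclusion_table():
    """20 controls, one violating each rule: one missing insulin (as a case),
    one hypoglycemic, one extreme BMI outlier."""
    pids = [f"C{i:02d}" for i in range(20)]
    e = _full_attendance_exams(pids)
    rng = np.random.default_rng(0)
    e["bmi"] = 25.0 + rng.normal(0, 0.5, len(e))  # needs spread for the SD rule
    e.loc[(e["participant_id"] == "C01") & (e["exam_index"] == 2), "fasting_insulin"] = np.nan
    e.loc[(e["participant_id"] == "C02") & (e["exam_index"] == 1), "fpg"] = 60.0
    e.loc[(e["participant_id"] == "C03") & (e["exam_index"] == 1), "bmi"] = 25.0 + 6 * 0.5
    # make C03 the only >5 SD outlier at exam 1 by construction
    bmi1 = e.loc[e["exam_index"] == 1, "bmi"]
    m, s = bmi1.mean(), bmi1.std(ddof=1)
    e.loc[(e["participant_id"] == "C03") & (e["exam_index"] == 1), "bmi"] = m + 5.5 * s
    sample = _participants([{"participant_id": pid} for pid in pids])
    sample.loc[sample["participant_id"] == "C01", "classification_exam"] = 2
    return sample, e


class TestExclusionCascade:
    def test_each_rule_fires_once_and_conserves(self):
        sample, e = _toy_exclusion_table()
        clean, log = apply_exclusions(sample, e)
        rules = [r for r, _, _ in log.entries]
        assert rules == ["missing_required_fields", "fpg_below_70", "outlier_5sd"]
        assert all(n == 1 for _, n, _ in log.entries)
        assert len(sample) == len(clean) + log.total_removed
        assert log.removed_ids() == {"C01", "C02", "C03"}

    def test_value_at_exactly_5sd_retained(self):
        sample, e = _toy_exclusion_table()
        # move the outlier to exactly mean + 5 SD of the remaining sample
        sub = e[~e["participant_id"].isin(["C01", "C02"])]
        sample = sample[~sample["participant_id"].isin(["C01", "C02"])]
        bmi1 = sub.loc[sub["exam_index"] == 1, "bmi"].copy()
        others = bmi1[sub.loc[sub["exam_index"] == 1, "participant_id"] != "C03"]

        def put(x):
            out = sub.copy()
            out.loc[(out["participant_id"] == "C03") & (out["exam_index"] == 1), "bmi"] = x
            return out

        # boundary value: exactly mean + 5 SD of the rest of the sample;
        # the rule is strict (>), so the boundary itself is retained
        v = others.mean() + 5.0 * others.std(ddof=1)
        clean, log = apply_exclusions(sample, put(v))
        assert "C03" not in log.removed_ids()
        clean, log = apply_exclusions(sample, put(v * 1.05))
        assert "C03" in log.removed_ids()

    def test_unknown_rule_rejected(self):
        sample, e = _toy_exclusion_table()
        with pytest.raises(ConfigurationError, match="unknown"):
            apply_exclusions(sample, e, rules=("fpg_below_70", "bogus"))

    def test_hypoglycemia_threshold_direct(self):
        pids = [f"C{i}" for i in range(10)]
        e = _full_attendance_exams(pids)
        e.loc[(e["participant_id"] == "C4") & (e["exam_index"] == 2), "fpg"] = 65.0
        sample = _participants([{"participant_id": pid} for pid in pids])
        clean, log = apply_exclusions(sample, e, rules=("fpg_below_70",))
        assert len(clean) == 9
        assert log.entries == [("fpg_below_70", 1, ("C4",))]


class TestTimelineAlignment:
    def _aligned(self, class_exam):
        cases = _participants([{
            "participant_id": "A", "diagnosis_time": 8.0 if class_exam == 2 else 18.0,
        }])
        cases["subtype"] = "SIDD"
        cases["classification_exam"] = class_exam
        cases["classification_time"] = 10.0 if class_exam == 2 else 20.0
        controls = _participants([{"participant_id": "B"}])
        e = _full_attendance_exams(["A", "B"])
        return align_timeline(cases, controls, e)

    def test_case_classified_at_exam3(self):
        obs = self._aligned(3)
        case = obs[obs["participant_id"] == "A"].set_index("exam_index")
        assert list(case["relative_label"]) == ["20y-pre", "10y-pre", "classification"]
        assert list(case["relative_time"]) == [-20.0, -10.0, 0.0]

    def test_case_classified_at_exam2(self):
        obs = self._aligned(2)
        case = obs[obs["participant_id"] == "A"].set_index("exam_index")
        assert list(case["relative_label"]) == ["10y-pre", "classification", "10y-post"]
        assert list(case["relative_time"]) == [-10.0, 0.0, 10.0]

    def test_controls_keep_calendar_labels(self):
        obs = self._aligned(2)
        ctrl = obs[obs["participant_id"] == "B"]
        assert list(ctrl["relative_label"]) == ["10y-pre", "classification", "10y-post"]
        assert (ctrl["group"] == "control").all()
        assert list(ctrl["relative_time"]) == [-10.0, 0.0, 10.0]

    def test_case_without_classification_rejected(self):
        cases = _participants([{"participant_id": "A", "diagnosis_time": 8.0}])
        cases["subtype"] = "SIDD"
        cases["classification_exam"] = np.nan
        cases["classification_time"] = np.nan
        with pytest.raises(ContractError):
            align_timeline(cases, _participants([]), _full_attendance_exams(["A"]))

    def test_every_attended_exam_appears_exactly_once(self, small_cohort):
        p, e = small_cohort
        obs = align_timeline_from_truth(p, e)
        assert len(obs) == len(e)
        assert not obs.duplicated(["participant_id", "exam_index"]).any()

    def test_classification_lag_bounds_on_simulated_cohort(self, small_cohort):
        p, e = small_cohort
        cases, log = select_incident_cases(p, e)
        assert (cases["diagnosis_to_exam_years"] >= 0).all()
        assert (cases["diagnosis_to_exam_years"] <= 5).all()
        assert len(p[p["diagnosis_time"].notna()]) == len(cases) + log.total_removed
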