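"""Cohort selection: windows, index dates, exclusions, attrition."""

import datetime as dt
import itertools

import pytest

from nrt_pathways.cohort import (
    EXCLUSION_REASONS,
    StudyWindow,
    build_attrition_table,
    classify_nonpatch_only,
    compute_windows,
    evaluate_eligibility,
    find_index_date,
    select_cohort,
)
from nrt_pathways.records import (
    NRT_CLASSES,
    PatientRecord,
    PracticeRecord,
    PrescriptionEvent,
)

D = dt.date
WINDOW = StudyWindow()


def practice(**kwargs) -> PracticeRecord:
    defaults = dict(
        practice_id="pr1",
        vision_date=D(2000, 1, 1),
        amr_date=D(2001, 1, 1),
        last_collection_date=D(2013, 6, 30),
    )
    defaults.update(kwargs)
    return PracticeRecord(**defaults)


def patient(**kwargs) -> PatientRecord:
    defaults = dict(
        patient_id="p1",
        practice_id="pr1",
        year_of_birth=1970,
        gender="male",
        registration_date=D(2005, 1, 1),
    )
    defaults.update(kwargs)
    return PatientRecord(**defaults)


def rx(date, drug_class="NRT_patch", strength="", pid="p1") -> PrescriptionEvent:
    return PrescriptionEvent(pid, date, drug_class, strength)


class TestComputeWindows:
    def test_baseline_is_latest_of_three_dates(self):
        start, _ = compute_windows(
            patient(registration_date=D(2005, 1, 1)),
            practice(vision_date=D(2004, 1, 1), amr_date=D(2006, 6, 1)),
        )
        assert start == D(2006, 6, 1)

    def test_absent_transfer_out_uses_last_collection(self):
        _, end = compute_windows(patient(), practice(last_collection_date=D(2012, 7, 1)))
        assert end == D(2012, 7, 1)

    def test_transfer_out_caps_followup(self):
        _, end = compute_windows(
            patient(transfer_out_date=D(2010, 1, 1)), practice()
        )
        assert end == D(2010, 1, 1)

    def test_degenerate_tie_of_baseline_dates(self):
        tie = D(2005, 1, 1)
        start, _ = compute_windows(
            patient(registration_date=tie),
            practice(vision_date=tie, amr_date=tie),
        )
        assert start == tie


class TestFindIndexDate:
    def test_window_boundaries_inclusive(self):
        events = [rx(D(2007, 12, 31)), rx(D(2008, 1, 1))]
        assert find_index_date(events, WINDOW) == D(2008, 1, 1)

    def test_no_patch_events_gives_absent(self):
        events = [rx(D(2009, 1, 1), "NRT_gum"), rx(D(2009, 2, 1), "NRT_inhalator")]
        assert find_index_date(events, WINDOW) is None

    def test_earliest_in_window_patch_wins(self):
        events = [rx(D(2009, 2, 1)), rx(D(2009, 5, 1)), rx(D(2011, 12, 31))]
        assert find_index_date(events, WINDOW) == D(2009, 2, 1)


class TestEvaluateEligibility:
    def test_clean_patient_included(self):
        result = evaluate_eligibility(patient(), practice(), [rx(D(2008, 6, 1))], WINDOW)
        assert result.status == "included"
        assert result.exclusion_reasons == []
        assert result.index_date == D(2008, 6, 1)
        assert result.age_at_index == 38

    def test_nonpatch_on_day_minus_14_is_allowed(self):
        # The two-week combination allowance includes day -14 itself.
        events = [rx(D(2008, 5, 18), "NRT_gum"), rx(D(2008, 6, 1))]
        result = evaluate_eligibility(patient(), practice(), events, WINDOW)
        assert result.status == "included"

    def test_nonpatch_on_day_minus_15_excludes(self):
        events = [rx(D(2008, 5, 17), "NRT_gum"), rx(D(2008, 6, 1))]
        result = evaluate_eligibility(patient(), practice(), events, WINDOW)
        assert result.exclusion_reasons == ["prior_nonpatch"]

    def test_varenicline_day_before_index_excludes(self):
        events = [rx(D(2008, 5, 31), "varenicline"), rx(D(2008, 6, 1))]
        result = evaluate_eligibility(patient(), practice(), events, WINDOW)
        assert result.status == "excluded"
        assert result.exclusion_reasons == ["prior_bup_var"]

    def test_multiple_failures_all_recorded(self):
        events = [rx(D(2008, 1, 15), "bupropion"), rx(D(2008, 6, 1))]
        result = evaluate_eligibility(
            patient(year_of_birth=1992), practice(), events, WINDOW
        )
        assert result.exclusion_reasons == ["under_18", "prior_bup_var"]

    def test_sequential_mode_short_circuits(self):
        events = [rx(D(2008, 1, 15), "bupropion"), rx(D(2008, 6, 1))]
        result = evaluate_eligibility(
            patient(year_of_birth=1992), practice(), events, WINDOW, sequential=True
        )
        assert result.exclusion_reasons == ["under_18"]

    def test_baseline_boundary_183_days(self):
        # Exactly 183 days of baseline is sufficient; 182 is not.
        ok = evaluate_eligibility(
            patient(registration_date=D(2008, 6, 1) - dt.timedelta(days=183)),
            practice(),
            [rx(D(2008, 6, 1))],
            WINDOW,
        )
        assert ok.status == "included"
        short = evaluate_eligibility(
            patient(registration_date=D(2008, 6, 1) - dt.timedelta(days=182)),
            practice(),
            [rx(D(2008, 6, 1))],
            WINDOW,
        )
        assert short.exclusion_reasons == ["short_baseline"]

    def test_followup_boundary_14_days(self):
        ok = evaluate_eligibility(
            patient(transfer_out_date=D(2008, 6, 15)), practice(), [rx(D(2008, 6, 1))], WINDOW
        )
        assert ok.status == "included"
        short = evaluate_eligibility(
            patient(transfer_out_date=D(2008, 6, 14)), practice(), [rx(D(2008, 6, 1))], WINDOW
        )
        assert short.exclusion_reasons == ["short_followup"]


class TestClassifyNonpatchOnly:
    SINGLETONS = {
        "NRT_gum": "gum_only",
        "NRT_tablet": "tablet_only",
        "NRT_inhalator": "inhalator_only",
        "NRT_lozenge": "lozenge_only",
        "NRT_oral_spray": "oral_spray_only",
        "NRT_nasal_spray": "nasal_spray_only",
    }

    def test_repeat_issues_of_one_class_are_one_category(self):
        events = [rx(D(2009, 1, 1), "NRT_inhalator"), rx(D(2009, 2, 1), "NRT_inhalator")]
        assert classify_nonpatch_only(events, WINDOW) == "inhalator_only"

    def test_every_nonempty_subset_maps_to_exactly_one_category(self):
        nonpatch = [c for c in NRT_CLASSES if c != "NRT_patch"]
        for r in range(1, len(nonpatch) + 1):
            for subset in itertools.combinations(nonpatch, r):
                events = [rx(D(2009, 1, 1 + i), c) for i, c in enumerate(subset)]
                category = classify_nonpatch_only(events, WINDOW)
                if len(subset) == 1:
                    assert category == self.SINGLETONS[subset[0]]
                else:
                    assert category == "multiple_nonpatch"

    def test_precondition_violations_raise(self):
        with pytest.raises(ValueError):
            classify_nonpatch_only([], WINDOW)
        with pytest.raises(ValueError):
            classify_nonpatch_only([rx(D(2009, 1, 1), "NRT_patch")], WINDOW)


def brute_force_eligible(patient_rec, practice_rec, events, window) -> bool:
    """Independent straight-line re-evaluation of all six criteria."""
    patch_dates = sorted(
        e.date for e in events
        if e.drug_class == "NRT_patch" and window.start <= e.date <= window.end
    )
    if not patch_dates:
        return False
    index = patch_dates[0]
    baseline = max(
        patient_rec.registration_date, practice_rec.vision_date, practice_rec.amr_date
    )
    end = practice_rec.last_collection_date
    if patient_rec.transfer_out_date is not None and patient_rec.transfer_out_date < end:
        end = patient_rec.transfer_out_date
    if index.year - patient_rec.year_of_birth < 18:
        return False
    if (index - baseline).days < 183:
        return False
    if (end - index).days < 14:
        return False
    for e in events:
        if e.drug_class == "NRT_patch" and e.date < index:
            return False
        if (
            e.drug_class.startswith("NRT_")
            and e.drug_class != "NRT_patch"
            and e.date < index - dt.timedelta(days=14)
        ):
            return False
        if e.drug_class in ("bupropion", "varenicline") and e.date < index:
            return False
    return True


class TestCohortInvariants:
    def test_partition_and_conservation(self, default_dataset, default_result):
        """Every NRT-cohort patient lands in exactly one arm, and the arms add up."""
        eligibility = default_result.eligibility
        statuses = [r.status for r in eligibility.values()]
        nonpatch = statuses.count("nonpatch_only")
        included = statuses.count("included")
        excluded = statuses.count("excluded")
        outside = statuses.count("no_patch_in_window")
        assert nonpatch + included + excluded + outside == len(eligibility)
        table = default_result.attrition
        assert table["nrt_cohort"].count == nonpatch + included + excluded
        assert table["patch_cohort"].count == included + excluded
        assert table["study_population"].count == included
        assert included <= table["patch_cohort"].count

    def test_included_patients_pass_brute_force_recheck(self, default_dataset, default_result):
        by_patient = default_dataset.prescriptions_by_patient()
        for pid, result in default_result.eligibility.items():
            oracle = brute_force_eligible(
                default_dataset.patients[pid],
                default_dataset.practice_of(pid),
                by_patient.get(pid, []),
                default_result.window,
            )
            assert oracle == (result.status == "included"), pid

    def test_window_shrink_never_admits_outside_index(self, default_dataset):
        shrunk = StudyWindow(D(2009, 1, 1), D(2010, 12, 31))
        results = select_cohort(default_dataset, shrunk)
        for r in results.values():
            if r.status == "included":
                assert shrunk.contains(r.index_date)


class TestAttritionTable:
    def test_toy_fixture_plants_each_exclusion_once(self, toy_result):
        table = toy_result.attrition
        for reason in EXCLUSION_REASONS:
            assert table[reason].count == 1, reason
        assert table["study_population"].count == 6
        assert table["nonpatch_only"].count == 1

    def test_zero_patient_dataset_renders_zero_percent(self):
        table = build_attrition_table({})
        for row in table.rows:
            assert row.count == 0
            assert row.percent == 0.0

    def test_nonpatch_breakdown_percentages_sum_to_100(self, default_result):
        table = default_result.attrition
        total = sum(
            table[c].percent
            for c in (
                "gum_only", "tablet_only", "inhalator_only", "lozenge_only",
                "oral_spray_only", "nasal_spray_only", "multiple_nonpatch",
            )
        )
        assert total == pytest.approx(100.0, abs=0.05)
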