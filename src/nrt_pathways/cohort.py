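"""Incident-user cohort selection with full attrition accounting.

The cohort comprises adults whose first-ever nicotine-patch prescription
(the index date) falls inside the study window, with at least six months
(183 days) of quality-controlled baseline data before index and at least
14 days of follow-up after it, and no history of NRT or of
bupropion/varenicline before index — except that non-patch NRT issued in
the two weeks up to the index patch is allowed, so that combination
regimens started slightly before the patch are not discarded.

Patients with NRT in the window but no patch form a separate
"non-patch-only" arm that is described (seven-way product breakdown) and
then set aside.  Exclusion reasons are evaluated exhaustively rather than
short-circuited, so one patient can contribute to several attrition rows
and the per-criterion percentages may sum past 100.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .records import Dataset, PatientRecord, PracticeRecord, PrescriptionEvent
from .rounding import round_half_up

#: Minimum quality-controlled baseline, in days ("6 months").
MIN_BASELINE_DAYS = 183
#: Minimum follow-up after the index date, in days.
MIN_FOLLOWUP_DAYS = 14
#: Non-patch NRT within this many days before index is tolerated
#: (possible start of combination therapy), inclusive of day -14.
PRE_INDEX_ALLOWANCE_DAYS = 14
#: Minimum age at index, in completed years.
MIN_AGE = 18

EXCLUSION_REASONS = (
    "under_18",
    "short_baseline",
    "short_followup",
    "prior_patch",
    "prior_nonpatch",
    "prior_bup_var",
)

NONPATCH_CATEGORIES = (
    "gum_only",
    "tablet_only",
    "inhalator_only",
    "lozenge_only",
    "oral_spray_only",
    "nasal_spray_only",
    "multiple_nonpatch",
)


@dataclass(frozen=True)
class StudyWindow:
    """Closed calendar interval for identifying index prescriptions."""

    start: dt.date = dt.date(2008, 1, 1)
    end: dt.date = dt.date(2011, 12, 31)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("study window start must precede end")

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


@dataclass
class EligibilityResult:
    """Outcome of evaluating one patient against the cohort rules.

    ``status`` is one of ``included``, ``excluded``, ``nonpatch_only``
    (NRT in the window but never a patch) or ``no_patch_in_window`` (no
    NRT in the window at all — outside the NRT cohort).
    """

    patient_id: str
    status: str
    index_date: dt.date | None = None
    baseline_start: dt.date | None = None
    followup_end: dt.date | None = None
    age_at_index: int | None = None
    exclusion_reasons: list[str] = field(default_factory=list)
    nonpatch_category: str | None = None


def compute_windows(
    patient: PatientRecord, practice: PracticeRecord
) -> tuple[dt.date, dt.date]:
    """Baseline start and follow-up end for one patient.

    Baseline starts at the latest of the registration, Vision and AMR
    dates; follow-up ends at the earlier of transfer-out and the
    practice's last data collection.
    """
    baseline_start = max(
        patient.registration_date, practice.vision_date, practice.amr_date
    )
    followup_end = practice.last_collection_date
    if patient.transfer_out_date is not None:
        followup_end = min(followup_end, patient.transfer_out_date)
    return baseline_start, followup_end


def find_index_date(
    prescriptions: list[PrescriptionEvent], window: StudyWindow
) -> dt.date | None:
    """Earliest patch prescription date within the (closed) window."""
    dates = [e.date for e in prescriptions if e.is_patch and window.contains(e.date)]
    return min(dates) if dates else None


def age_at(index_date: dt.date, year_of_birth: int) -> int:
    # Year precision only: the schema carries no birth month.
    return index_date.year - year_of_birth


def evaluate_eligibility(
    patient: PatientRecord,
    practice: PracticeRecord,
    prescriptions: list[PrescriptionEvent],
    window: StudyWindow = StudyWindow(),
    *,
    sequential: bool = False,
) -> EligibilityResult:
    """Apply the six cohort criteria to one patient.

    All failing criteria are recorded in a fixed order (age, baseline,
    follow-up, prior patch, prior non-patch, prior bupropion/varenicline);
    with ``sequential=True`` evaluation stops at the first failure
    instead, for sensitivity analysis of the attrition accounting.
    """
    index_date = find_index_date(prescriptions, window)
    if index_date is None:
        nrt_in_window = [e for e in prescriptions if e.is_nrt and window.contains(e.date)]
        if nrt_in_window:
            return EligibilityResult(
                patient_id=patient.patient_id,
                status="nonpatch_only",
                nonpatch_category=classify_nonpatch_only(prescriptions, window),
            )
        return EligibilityResult(patient_id=patient.patient_id, status="no_patch_in_window")

    baseline_start, followup_end = compute_windows(patient, practice)
    age = age_at(index_date, patient.year_of_birth)

    reasons: list[str] = []

    def check(reason: str, failed: bool) -> bool:
        if failed:
            reasons.append(reason)
        return failed

    checks = (
        ("under_18", lambda: age < MIN_AGE),
        ("short_baseline", lambda: (index_date - baseline_start).days < MIN_BASELINE_DAYS),
        ("short_followup", lambda: (followup_end - index_date).days < MIN_FOLLOWUP_DAYS),
        ("prior_patch", lambda: any(e.is_patch and e.date < index_date for e in prescriptions)),
        (
            "prior_nonpatch",
            # Strictly more than 14 days before index; day -14 itself is allowed.
            lambda: any(
                e.is_nrt
                and not e.is_patch
                and (index_date - e.date).days > PRE_INDEX_ALLOWANCE_DAYS
                and e.date < index_date
                for e in prescriptions
            ),
        ),
        (
            "prior_bup_var",
            lambda: any(
                e.drug_class in ("bupropion", "varenicline") and e.date < index_date
                for e in prescriptions
            ),
        ),
    )
    for reason, failed in checks:
        if check(reason, failed()) and sequential:
            break

    return EligibilityResult(
        patient_id=patient.patient_id,
        status="excluded" if reasons else "included",
        index_date=index_date,
        baseline_start=baseline_start,
        followup_end=followup_end,
        age_at_index=age,
        exclusion_reasons=reasons,
    )


def classify_nonpatch_only(
    prescriptions: list[PrescriptionEvent], window: StudyWindow
) -> str:
    """Seven-way product breakdown for patients with no patch in the window."""
    classes = {
        e.drug_class
        for e in prescriptions
        if e.is_nrt and window.contains(e.date)
    }
    if not classes:
        raise ValueError("classify_nonpatch_only requires >=1 NRT event in window")
    if "NRT_patch" in classes:
        raise ValueError("classify_nonpatch_only requires zero patch events in window")
    if len(classes) > 1:
        return "multiple_nonpatch"
    (only,) = classes
    return {
        "NRT_gum": "gum_only",
        "NRT_tablet": "tablet_only",
        "NRT_inhalator": "inhalator_only",
        "NRT_lozenge": "lozenge_only",
        "NRT_oral_spray": "oral_spray_only",
        "NRT_nasal_spray": "nasal_spray_only",
    }[only]


def select_cohort(
    dataset: Dataset,
    window: StudyWindow = StudyWindow(),
    *,
    sequential: bool = False,
) -> dict[str, EligibilityResult]:
    """Evaluate every patient in the dataset; keyed by patient_id."""
    by_patient = dataset.prescriptions_by_patient()
    results: dict[str, EligibilityResult] = {}
    for patient_id, patient in dataset.patients.items():
        results[patient_id] = evaluate_eligibility(
            patient,
            dataset.practices[patient.practice_id],
            by_patient.get(patient_id, []),
            window,
            sequential=sequential,
        )
    return results


@dataclass
class AttritionRow:
    label: str
    count: int
    denominator: int

    @property
    def percent(self) -> float:
        if self.denominator == 0:
            return 0.0
        return round_half_up(100.0 * self.count / self.denominator, 2)


@dataclass
class AttritionTable:
    """Machine-readable stepwise account of cohort selection.

    Percentages use the denominator stated for each row: the non-patch
    product breakdown is over the non-patch-only count; the exclusion rows
    and the final study population are over the patch cohort; the patch
    and non-patch arms are over the total NRT cohort.  Exclusion counts
    overlap (one patient may fail several criteria).
    """

    rows: list[AttritionRow]

    def __getitem__(self, label: str) -> AttritionRow:
        for row in self.rows:
            if row.label == label:
                return row
        raise KeyError(label)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "row": r.label,
                    "n": r.count,
                    "denominator": r.denominator,
                    "percent": r.percent,
                }
                for r in self.rows
            ]
        )


def build_attrition_table(results: dict[str, EligibilityResult]) -> AttritionTable:
    """Attrition table over all evaluated patients."""
    in_cohort = [r for r in results.values() if r.status != "no_patch_in_window"]
    nonpatch = [r for r in in_cohort if r.status == "nonpatch_only"]
    patch_cohort = [r for r in in_cohort if r.status in ("included", "excluded")]
    included = [r for r in patch_cohort if r.status == "included"]

    total = len(in_cohort)
    rows = [
        AttritionRow("nrt_cohort", total, total),
        AttritionRow("nonpatch_only", len(nonpatch), total),
    ]
    for category in NONPATCH_CATEGORIES:
        rows.append(
            AttritionRow(
                category,
                sum(1 for r in nonpatch if r.nonpatch_category == category),
                len(nonpatch),
            )
        )
    rows.append(AttritionRow("patch_cohort", len(patch_cohort), total))
    for reason in EXCLUSION_REASONS:
        rows.append(
            AttritionRow(
                reason,
                sum(1 for r in patch_cohort if reason in r.exclusion_reasons),
                len(patch_cohort),
            )
        )
    # Combined prior-NRT history row (patch or non-patch), as conventionally
    # reported in selection flowcharts.
    rows.append(
        AttritionRow(
            "prior_nrt_any",
            sum(
                1
                for r in patch_cohort
                if {"prior_patch", "prior_nonpatch"} & set(r.exclusion_reasons)
            ),
            len(patch_cohort),
        )
    )
    rows.append(AttritionRow("study_population", len(included), len(patch_cohort)))
    return AttritionTable(rows)


def eligibility_frame(results: dict[str, EligibilityResult]):
    """One row per patient, CSV-friendly."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "status": r.status,
                "index_date": r.index_date,
                "baseline_start": r.baseline_start,
                "followup_end": r.followup_end,
                "age_at_index": r.age_at_index,
                "exclusion_reasons": ";".join(r.exclusion_reasons),
                "nonpatch_category": r.nonpatch_category or "",
            }
            for r in results.values()
        ]
    )
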