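"""Core record types for the prescribing analysis.

Three flat tables describe a primary-care dataset: practices (data-quality
window dates), patients (demographics, registration and clinical flags) and
prescriptions (dated drug issues).  Everything downstream — cohort
selection, episode construction, regimen classification — consumes these
types.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

#: Closed vocabulary of drug classes.  The seven NRT delivery forms plus the
#: two non-NRT smoking-cessation drugs (which never enter NRT episodes but
#: drive an exclusion criterion).
NRT_CLASSES: tuple[str, ...] = (
    "NRT_patch",
    "NRT_gum",
    "NRT_tablet",
    "NRT_inhalator",
    "NRT_lozenge",
    "NRT_oral_spray",
    "NRT_nasal_spray",
)
NON_NRT_CLASSES: tuple[str, ...] = ("bupropion", "varenicline")
DRUG_CLASSES: tuple[str, ...] = NRT_CLASSES + NON_NRT_CLASSES

#: Canonical display order of NRT classes in tables and pathway signatures:
#: patch first (the anchor product), then the faster-acting forms.
NRT_CLASS_ORDER: dict[str, int] = {c: i for i, c in enumerate(NRT_CLASSES)}

#: Clinical conditions summarised at baseline.
COMORBIDITIES: tuple[str, ...] = ("CVD", "asthma", "COPD", "diabetes", "stroke")

GENDERS: tuple[str, ...] = ("male", "female")


class DatasetError(ValueError):
    """Base class for dataset validation failures."""


class SchemaError(DatasetError):
    """A required column is missing or a value cannot be parsed."""


class VocabularyError(DatasetError):
    """A value falls outside a closed vocabulary (e.g. drug_class)."""


class ReferentialError(DatasetError):
    """A foreign key does not resolve."""


@dataclass(frozen=True)
class PracticeRecord:
    """A general practice contributing records.

    ``vision_date`` is the date the practice started using the Vision
    practice-management software; ``amr_date`` (Acceptable Mortality
    Reporting) marks the start of quality-assured recording.  Data before
    the later of the two are considered incomplete, and nothing after
    ``last_collection_date`` is observed.
    """

    practice_id: str
    vision_date: dt.date
    amr_date: dt.date
    last_collection_date: dt.date

    def __post_init__(self) -> None:
        if self.vision_date > self.last_collection_date:
            raise DatasetError(
                f"practice {self.practice_id}: vision_date after last_collection_date"
            )
        if self.amr_date > self.last_collection_date:
            raise DatasetError(
                f"practice {self.practice_id}: amr_date after last_collection_date"
            )


@dataclass(frozen=True)
class PatientRecord:
    """A registered patient.

    ``comorbidities`` maps condition name to the date of its first record;
    history may legitimately predate registration.  ``townsend_quintile``
    is the area-deprivation quintile (1 most affluent, 5 least affluent) or
    ``None`` when unknown.  ``pregnant_at_index`` is a cohort-time flag
    resolved by the data provider.
    """

    patient_id: str
    practice_id: str
    year_of_birth: int
    gender: str
    registration_date: dt.date
    transfer_out_date: dt.date | None = None
    townsend_quintile: int | None = None
    pregnant_at_index: bool = False
    comorbidities: dict[str, dt.date] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise VocabularyError(
                f"patient {self.patient_id}: unknown gender {self.gender!r}"
            )
        if self.transfer_out_date is not None and (
            self.registration_date > self.transfer_out_date
        ):
            raise DatasetError(
                f"patient {self.patient_id}: registration after transfer out"
            )
        if self.townsend_quintile is not None and self.townsend_quintile not in (
            1,
            2,
            3,
            4,
            5,
        ):
            raise VocabularyError(
                f"patient {self.patient_id}: townsend_quintile must be 1-5, "
                f"got {self.townsend_quintile!r}"
            )
        for name in self.comorbidities:
            if name not in COMORBIDITIES:
                raise VocabularyError(
                    f"patient {self.patient_id}: unknown comorbidity {name!r}"
                )


@dataclass(frozen=True, order=True)
class PrescriptionEvent:
    """One dated drug issue — the pipeline's atomic input.

    Strength labels are opaque strings (e.g. ``"21 mg/24 hours"``) matched
    exactly; no dose arithmetic is ever performed on them.  Same-day
    duplicate issues are legal and are retained on load.
    """

    patient_id: str
    date: dt.date
    drug_class: str
    strength_label: str = ""

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise VocabularyError(f"unknown drug_class {self.drug_class!r}")

    @property
    def is_nrt(self) -> bool:
        return self.drug_class in NRT_CLASSES

    @property
    def is_patch(self) -> bool:
        return self.drug_class == "NRT_patch"


@dataclass
class Dataset:
    """A validated trio of record collections.

    Prescriptions are kept sorted by (patient_id, date, drug_class,
    strength_label) so downstream behaviour is a pure function of file
    content.  ``practices`` and ``patients`` preserve input order keyed by
    their ids.
    """

    practices: dict[str, PracticeRecord]
    patients: dict[str, PatientRecord]
    prescriptions: list[PrescriptionEvent]

    def __post_init__(self) -> None:
        for patient in self.patients.values():
            if patient.practice_id not in self.practices:
                raise ReferentialError(
                    f"patient {patient.patient_id}: practice "
                    f"{patient.practice_id!r} not found"
                )
        for event in self.prescriptions:
            if event.patient_id not in self.patients:
                raise ReferentialError(
                    f"prescription for unknown patient {event.patient_id!r}"
                )
        self.prescriptions.sort(
            key=lambda e: (e.patient_id, e.date, e.drug_class, e.strength_label)
        )

    def prescriptions_for(self, patient_id: str) -> list[PrescriptionEvent]:
        """All prescription events of one patient, in sorted order."""
        return [e for e in self.prescriptions if e.patient_id == patient_id]

    def prescriptions_by_patient(self) -> dict[str, list[PrescriptionEvent]]:
        """Events grouped per patient (single pass over the sorted list)."""
        out: dict[str, list[PrescriptionEvent]] = {}
        for event in self.prescriptions:
            out.setdefault(event.patient_id, []).append(event)
        return out

    def practice_of(self, patient_id: str) -> PracticeRecord:
        return self.practices[self.patients[patient_id].practice_id]

    @property
    def n_patients(self) -> int:
        return len(self.patients)
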