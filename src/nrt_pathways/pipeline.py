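"""End-to-end orchestration: dataset in, tables and headline stats out."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from .cohort import (
    AttritionTable,
    EligibilityResult,
    StudyWindow,
    build_attrition_table,
    select_cohort,
)
from .episodes import (
    DiscontinuationStatus,
    Episode,
    build_episodes,
    discontinuation,
    trim_to_followup,
)
from .records import Dataset
from .regimens import (
    ClassifiedEpisode,
    classify_patient,
    decompose_patient,
    pathway_signature,
)
from .reporting import (
    BaselineSummary,
    RegimenByYearTable,
    baseline_summary,
    headline_stats,
    pregnancy_initial_nrt,
    regimen_by_year,
    top_pathways,
)


@dataclass
class PipelineResult:
    """Everything the analysis produces for one dataset."""

    window: StudyWindow
    eligibility: dict[str, EligibilityResult]
    attrition: AttritionTable
    episodes: dict[str, list[Episode]]
    classified: list[ClassifiedEpisode]
    signatures: dict[str, str]
    discontinuation: dict[str, DiscontinuationStatus]
    tables: dict[int, RegimenByYearTable]
    baseline: BaselineSummary | None
    headline: dict
    pathways: list = field(default_factory=list)

    @property
    def included_ids(self) -> list[str]:
        return [pid for pid, r in self.eligibility.items() if r.status == "included"]

    def initial_categories(self) -> dict[str, str]:
        return {c.patient_id: c.category for c in self.classified if c.ordinal == 1}

    def episodes_frame(self) -> pd.DataFrame:
        rows = []
        for pid, episodes in self.episodes.items():
            status = self.discontinuation[pid]
            for episode in episodes:
                rows.append(
                    {
                        "patient_id": pid,
                        "ordinal": episode.ordinal,
                        "start_date": episode.start_date,
                        "end_date": episode.end_date,
                        "start_year": episode.start_year,
                        "n_events": len(episode.events),
                        "class_set": ";".join(sorted(episode.class_set)),
                        "product_set": ";".join(
                            f"{c}:{s}" for c, s in sorted(episode.product_set)
                        ),
                        "discontinued_after_last": (
                            status.discontinued
                            if episode.ordinal == len(episodes)
                            else ""
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def regimens_frame(self) -> pd.DataFrame:
        from .regimens import product_display

        def render(products):
            return " & ".join(product_display(c, s) for c, s in products)

        return pd.DataFrame(
            [
                {
                    "patient_id": c.patient_id,
                    "ordinal": c.ordinal,
                    "start_year": c.start_year,
                    "category": c.category,
                    "first_line": render(c.pathway.first_line),
                    "add_on": render(c.pathway.add_on),
                    "signature": self.signatures[c.patient_id],
                }
                for c in self.classified
            ]
        )


def run_pipeline(
    dataset: Dataset,
    window: StudyWindow = StudyWindow(),
    *,
    sequential_exclusions: bool = False,
) -> PipelineResult:
    """Select the cohort, build episodes, classify regimens, summarise."""
    eligibility = select_cohort(dataset, window, sequential=sequential_exclusions)
    attrition = build_attrition_table(eligibility)
    by_patient = dataset.prescriptions_by_patient()

    episodes: dict[str, list[Episode]] = {}
    discontinuation_status: dict[str, DiscontinuationStatus] = {}
    classified: list[ClassifiedEpisode] = []
    signatures: dict[str, str] = {}

    for pid, result in eligibility.items():
        if result.status != "included":
            continue
        nrt_events = [
            e
            for e in by_patient[pid]
            if e.is_nrt and e.date >= result.index_date - dt.timedelta(days=14)
        ]
        nrt_events = trim_to_followup(nrt_events, result.followup_end)
        patient_episodes = build_episodes(nrt_events, result.index_date)
        episodes[pid] = patient_episodes
        discontinuation_status[pid] = discontinuation(
            patient_episodes, result.followup_end
        )
        classified.extend(classify_patient(pid, patient_episodes))
        signatures[pid] = pathway_signature(decompose_patient(pid, patient_episodes))

    tables = {ordinal: regimen_by_year(classified, ordinal) for ordinal in (1, 2, 3)}

    initial_category = {c.patient_id: c.category for c in classified if c.ordinal == 1}
    baseline = (
        baseline_summary(dataset.patients, eligibility, initial_category)
        if episodes
        else None
    )

    nonpatch_prior_bup_var = _count_nonpatch_prior_bup_var(
        dataset, eligibility, window
    )
    headline = headline_stats(
        eligibility,
        episodes,
        classified,
        discontinuation_status,
        nonpatch_prior_bup_var=nonpatch_prior_bup_var,
    )
    headline["top_pathways"] = [
        {"rank": p.rank, "signature": p.signature, "n": p.count, "pct": p.pct}
        for p in top_pathways(signatures, 10)
    ]
    headline["pregnancy_initial_nrt"] = pregnancy_initial_nrt(
        dataset.patients, eligibility, initial_category
    )

    return PipelineResult(
        window=window,
        eligibility=eligibility,
        attrition=attrition,
        episodes=episodes,
        classified=classified,
        signatures=signatures,
        discontinuation=discontinuation_status,
        tables=tables,
        baseline=baseline,
        headline=headline,
    )


def _count_nonpatch_prior_bup_var(
    dataset: Dataset, eligibility: dict[str, EligibilityResult], window: StudyWindow
) -> int:
    """Non-patch-only patients with bupropion/varenicline before their
    first in-window NRT prescription."""
    by_patient = dataset.prescriptions_by_patient()
    count = 0
    for pid, result in eligibility.items():
        if result.status != "nonpatch_only":
            continue
        events = by_patient[pid]
        first_nrt = min(
            e.date for e in events if e.is_nrt and window.contains(e.date)
        )
        if any(
            e.drug_class in ("bupropion", "varenicline") and e.date < first_nrt
            for e in events
        ):
            count += 1
    return count
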