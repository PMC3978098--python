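"""Summary tables and headline statistics.

Every quantity here is descriptive arithmetic on counts the pipeline also
emits — counts and percentages per category and calendar year, ranked
pathway frequencies, and the handful of headline proportions (combination
share by year, repeat-episode rates, prior bupropion/varenicline use).
Table percentages are printed to two decimals and headline scalars to one,
both rounded half-up.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import EligibilityResult
from .episodes import DiscontinuationStatus, Episode
from .regimens import ALL_CATEGORIES, PATCH_CATEGORIES, ClassifiedEpisode
from .rounding import percent, round_half_up

OVERALL = "overall"


@dataclass
class RegimenByYearTable:
    """Counts and percentages of regimen categories by episode start year.

    One table per episode ordinal.  Columns are ``overall`` plus each
    start year present; the column N is the number of patients with an
    episode of that ordinal starting that year, and every percentage is
    over its column N.  First episodes can only carry the eight
    patch-containing categories (the cohort is anchored on a patch);
    later ordinals may also be patch-free ("other" categories).
    """

    ordinal: int
    categories: tuple[str, ...]
    counts: dict[str, Counter] = field(default_factory=dict)  # column -> category counts

    @property
    def columns(self) -> list[str]:
        years = sorted(c for c in self.counts if c != OVERALL)
        return [OVERALL] + years

    def n(self, column) -> int:
        return sum(self.counts[str(column)].values())

    def count(self, category: str, column) -> int:
        return self.counts[str(column)][category]

    def pct(self, category: str, column) -> float:
        return percent(self.count(category, column), self.n(column), 2)

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for column in self.columns:
            data[f"{column}_n"] = [self.count(c, column) for c in self.categories]
            data[f"{column}_pct"] = [self.pct(c, column) for c in self.categories]
        return pd.DataFrame(data, index=list(self.categories))

    @classmethod
    def from_counts(
        cls, ordinal: int, counts_by_column: dict[str, dict[str, int]]
    ) -> "RegimenByYearTable":
        """Build a table directly from per-column category counts.

        Used when re-deriving headline proportions from published counts
        as well as by the pipeline itself.
        """
        categories = PATCH_CATEGORIES if ordinal == 1 else ALL_CATEGORIES
        table = cls(ordinal=ordinal, categories=categories)
        for column, cat_counts in counts_by_column.items():
            table.counts[str(column)] = Counter(cat_counts)
        return table


def regimen_by_year(
    classified: list[ClassifiedEpisode], ordinal: int
) -> RegimenByYearTable:
    """Tabulate episodes of one ordinal by category and start year."""
    if ordinal not in (1, 2, 3):
        raise ValueError("tables are defined for ordinals 1-3")
    categories = PATCH_CATEGORIES if ordinal == 1 else ALL_CATEGORIES
    table = RegimenByYearTable(ordinal=ordinal, categories=categories)
    table.counts[OVERALL] = Counter()
    for episode in classified:
        if episode.ordinal != ordinal:
            continue
        table.counts[OVERALL][episode.category] += 1
        table.counts.setdefault(str(episode.start_year), Counter())[episode.category] += 1
    return table


def combination_share(table: RegimenByYearTable, column) -> float:
    """Percent of a column's episodes that are combination (not patch-only)."""
    column = str(column)
    if column not in table.counts:
        raise KeyError(f"no column {column!r} in ordinal-{table.ordinal} table")
    return percent(table.n(column) - table.count("patch_only", column), table.n(column), 1)


def combination_breakdown(table: RegimenByYearTable, column=OVERALL) -> dict[str, float]:
    """Each combination category's share among combination episodes, 1 dp."""
    column = str(column)
    combos = table.n(column) - table.count("patch_only", column)
    if combos == 0:
        return {}
    return {
        category: percent(table.count(category, column), combos, 1)
        for category in table.categories
        if category != "patch_only" and table.count(category, column) > 0
    }


@dataclass(frozen=True)
class PathwayRank:
    rank: int
    signature: str
    count: int
    pct: float


def top_pathways(
    signatures: dict[str, str] | list[str], k: int = 10, *, denominator: int | None = None
) -> list[PathwayRank]:
    """The k most frequent pathway signatures with % of the study population.

    Ties are broken by the canonical signature string so ranking is
    deterministic across runs.
    """
    values = list(signatures.values()) if isinstance(signatures, dict) else list(signatures)
    n = denominator if denominator is not None else len(values)
    counts = Counter(values)
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))[:k]
    return [
        PathwayRank(rank=i, signature=sig, count=c, pct=percent(c, n, 2))
        for i, (sig, c) in enumerate(ranked, start=1)
    ]


def summarize_values(values) -> dict[str, float]:
    """Min/max, mean/SD (n-1), median and quartiles (linear interpolation).

    The median of an even-sized sample is the mean of the two central
    order statistics; quartiles interpolate linearly between order
    statistics, so ages {1,2,3,4} give Q1 = 1.75 and Q3 = 3.25.
    """
    arr = np.asarray(sorted(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty sample")
    return {
        "n": int(arr.size),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "median": float(np.median(arr)),
        "q1": float(np.percentile(arr, 25, method="linear")),
        "q3": float(np.percentile(arr, 75, method="linear")),
    }


@dataclass
class BaselineSummary:
    """Baseline characteristics per initial-NRT category and overall."""

    groups: dict[str, dict]  # category (or "overall") -> summary mapping

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, summary in self.groups.items():
            row: dict = {"group": group, "n": summary["n"]}
            row.update({f"age_{k}": v for k, v in summary["age"].items() if k != "n"})
            for gender, (count, pct) in summary["gender"].items():
                row[f"{gender}_n"], row[f"{gender}_pct"] = count, pct
            for name, (count, pct) in summary["comorbidities"].items():
                row[f"{name}_n"], row[f"{name}_pct"] = count, pct
            for quintile, (count, pct) in summary["townsend"].items():
                row[f"townsend{quintile}_n"], row[f"townsend{quintile}_pct"] = count, pct
            row["pregnant_n"], row["pregnant_pct_of_women"] = summary["pregnancy"]
            rows.append(row)
        return pd.DataFrame(rows)


def baseline_summary(
    patients: dict,
    eligibility: dict[str, EligibilityResult],
    initial_category: dict[str, str],
) -> BaselineSummary:
    """Describe included patients, overall and per initial-NRT category.

    ``initial_category`` maps included patient_id to their episode-1
    regimen category.  Categories with no patients are omitted.
    """
    included = [pid for pid, r in eligibility.items() if r.status == "included"]
    groups: dict[str, list[str]] = {OVERALL: included}
    for category in PATCH_CATEGORIES:
        members = [pid for pid in included if initial_category.get(pid) == category]
        if members:
            groups[category] = members

    out: dict[str, dict] = {}
    for group, members in groups.items():
        ages = [eligibility[pid].age_at_index for pid in members]
        n = len(members)
        women = [pid for pid in members if patients[pid].gender == "female"]
        pregnant = sum(1 for pid in women if patients[pid].pregnant_at_index)
        summary = {
            "n": n,
            "age": summarize_values(ages),
            "gender": {
                g: (
                    sum(1 for pid in members if patients[pid].gender == g),
                    percent(sum(1 for pid in members if patients[pid].gender == g), n, 2),
                )
                for g in ("male", "female")
            },
            "comorbidities": {
                name: (
                    sum(1 for pid in members if name in patients[pid].comorbidities),
                    percent(
                        sum(1 for pid in members if name in patients[pid].comorbidities),
                        n,
                        2,
                    ),
                )
                for name in ("CVD", "asthma", "COPD", "diabetes", "stroke")
            },
            "townsend": {
                q: (
                    sum(1 for pid in members if patients[pid].townsend_quintile == q),
                    percent(
                        sum(1 for pid in members if patients[pid].townsend_quintile == q),
                        n,
                        2,
                    ),
                )
                for q in (1, 2, 3, 4, 5)
            },
            "pregnancy": (pregnant, percent(pregnant, len(women), 2)),
        }
        out[group] = summary
    return BaselineSummary(groups=out)


def repeat_episode_rate(n_with_repeat: int, n_included: int) -> float:
    """Percent of included patients starting a second episode, 1 dp."""
    return percent(n_with_repeat, n_included, 1)


def pooled_repeat_proportion(
    included_with_repeat: int, excluded_prior_nrt: int, patch_cohort: int
) -> float:
    """Repeat-NRT proportion pooling observed repeats with prior-history
    exclusions over the whole patch cohort, 1 dp.

    Patients excluded for NRT history are, by definition, repeat users; a
    cohort restricted to incident users understates repeat prescribing
    unless they are pooled back in.
    """
    return percent(included_with_repeat + excluded_prior_nrt, patch_cohort, 1)


def headline_stats(
    eligibility: dict[str, EligibilityResult],
    episodes_by_patient: dict[str, list[Episode]],
    classified: list[ClassifiedEpisode],
    discontinuation_by_patient: dict[str, DiscontinuationStatus],
    *,
    nonpatch_prior_bup_var: int = 0,
) -> dict:
    """Scalar report of the study's headline quantities.

    All percentages are pure arithmetic on counts also present in the
    returned mapping, so they can be recomputed independently from the
    CSV outputs.
    """
    included = [pid for pid, r in eligibility.items() if r.status == "included"]
    patch_cohort = [
        pid for pid, r in eligibility.items() if r.status in ("included", "excluded")
    ]
    nrt_cohort = [
        pid for pid, r in eligibility.items() if r.status != "no_patch_in_window"
    ]
    with_repeat = [pid for pid in included if len(episodes_by_patient[pid]) >= 2]
    excluded_prior_nrt = [
        pid
        for pid in patch_cohort
        if {"prior_patch", "prior_nonpatch"} & set(eligibility[pid].exclusion_reasons)
    ]
    # Over the whole NRT cohort: patch-cohort exclusions plus any count
    # supplied for the non-patch-only arm (whose criteria are never run).
    n_prior_bup_var = nonpatch_prior_bup_var + sum(
        1
        for pid in patch_cohort
        if "prior_bup_var" in eligibility[pid].exclusion_reasons
    )

    gaps = [
        gap
        for pid in included
        for gap in _gaps(episodes_by_patient[pid])
    ]
    followup_days = [
        (eligibility[pid].followup_end - eligibility[pid].index_date).days
        for pid in included
    ]
    discontinued = [
        pid for pid in included if discontinuation_by_patient[pid].discontinued
    ]

    category_of = {
        c.patient_id: c.category for c in classified if c.ordinal == 1
    }
    discontinuation_by_category = {}
    for category in PATCH_CATEGORIES:
        members = [pid for pid in included if category_of.get(pid) == category]
        if members:
            done = sum(1 for pid in members if discontinuation_by_patient[pid].discontinued)
            discontinuation_by_category[category] = percent(done, len(members), 1)

    report = {
        "n_included": len(included),
        "n_patch_cohort": len(patch_cohort),
        "n_nrt_cohort": len(nrt_cohort),
        "n_with_second_episode": len(with_repeat),
        "n_excluded_prior_nrt": len(excluded_prior_nrt),
        "n_prior_bup_var": n_prior_bup_var,
        "pct_second_episode": repeat_episode_rate(len(with_repeat), len(included)),
        "pct_pooled_repeat": pooled_repeat_proportion(
            len(with_repeat), len(excluded_prior_nrt), len(patch_cohort)
        ),
        "pct_prior_bup_var": percent(n_prior_bup_var, len(nrt_cohort), 1),
        "pct_discontinued": percent(len(discontinued), len(included), 1),
        "discontinuation_by_category": discontinuation_by_category,
    }
    if followup_days:
        report["followup_days"] = summarize_values(followup_days)
    if gaps:
        report["inter_episode_gap_days"] = summarize_values(gaps)
    return report


def _gaps(episodes: list[Episode]) -> list[int]:
    from .episodes import inter_episode_gaps

    return inter_episode_gaps(episodes)


def format_table(frame: pd.DataFrame, title: str) -> str:
    """Aligned text rendering of a machine-readable table."""
    return f"{title}\n{'-' * len(title)}\n{frame.to_string()}\n"


def pregnancy_initial_nrt(
    patients: dict,
    eligibility: dict[str, EligibilityResult],
    initial_category: dict[str, str],
) -> dict[str, float]:
    """Initial-regimen distribution among included pregnant women, 1 dp."""
    pregnant = [
        pid
        for pid, r in eligibility.items()
        if r.status == "included"
        and patients[pid].gender == "female"
        and patients[pid].pregnant_at_index
    ]
    if not pregnant:
        return {}
    counts = Counter(initial_category[pid] for pid in pregnant)
    return {
        category: percent(count, len(pregnant), 1)
        for category, count in sorted(counts.items())
    }
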