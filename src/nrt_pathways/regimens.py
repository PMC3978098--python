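"""Regimen categories and first-line/add-on pathway decomposition.

A regimen category summarises the set of NRT *types* (drug classes, not
strengths) appearing in an episode.  The patch is the anchor product:
patch alone is monotherapy, patch plus one other form is the matching
dual combination, and three or more distinct forms collapse into a single
"three-plus" category whether or not a patch is present.  Patch-free
episodes (possible only from the second episode onward, since the cohort
is anchored on a patch) fall into "other monotherapy" or "other dual".

The pathway view splits each episode's products into first-line (issued
on the episode's start date — for episode 1, including the permitted
two-week pre-index window) and add-on (first issued later in the
episode), mirroring how prescribing sequences are tabulated.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .episodes import Episode
from .records import NRT_CLASS_ORDER, NRT_CLASSES
from .rounding import percent

#: Categories for patch-containing episodes, in canonical table order.
PATCH_CATEGORIES = (
    "patch_only",
    "patch_gum",
    "patch_tablet",
    "patch_inhalator",
    "patch_lozenge",
    "patch_oral_spray",
    "patch_nasal_spray",
    "three_plus_types",
)
#: Additional categories for patch-free episodes (ordinals >= 2).
ALL_CATEGORIES = PATCH_CATEGORIES + ("other_monotherapy", "other_dual")

_DUAL_BY_PARTNER = {
    "NRT_gum": "patch_gum",
    "NRT_tablet": "patch_tablet",
    "NRT_inhalator": "patch_inhalator",
    "NRT_lozenge": "patch_lozenge",
    "NRT_oral_spray": "patch_oral_spray",
    "NRT_nasal_spray": "patch_nasal_spray",
}

#: Human-readable product nouns used in pathway signatures, following the
#: convention "<strength> <noun>" (e.g. "21 mg/24 hours patches").
CLASS_NOUNS = {
    "NRT_patch": "patches",
    "NRT_gum": "gum",
    "NRT_tablet": "tablets",
    "NRT_inhalator": "inhalator",
    "NRT_lozenge": "lozenges",
    "NRT_oral_spray": "oral spray",
    "NRT_nasal_spray": "nasal spray",
}


def classify_episode(class_set: frozenset[str] | set[str]) -> str:
    """Map an episode's set of NRT classes to its regimen category."""
    classes = set(class_set)
    if not classes:
        raise ValueError("class_set must be non-empty")
    unknown = classes - set(NRT_CLASSES)
    if unknown:
        raise ValueError(f"unknown NRT class(es): {sorted(unknown)}")
    if len(classes) >= 3:
        return "three_plus_types"
    has_patch = "NRT_patch" in classes
    if has_patch:
        if len(classes) == 1:
            return "patch_only"
        (partner,) = classes - {"NRT_patch"}
        return _DUAL_BY_PARTNER[partner]
    return "other_monotherapy" if len(classes) == 1 else "other_dual"


def product_display(drug_class: str, strength_label: str) -> str:
    """Canonical product name, e.g. ``'21 mg/24 hours patches'``."""
    noun = CLASS_NOUNS[drug_class]
    return f"{strength_label} {noun}" if strength_label else noun


def _product_key(product: tuple[str, str]) -> tuple[int, str]:
    drug_class, strength = product
    return (NRT_CLASS_ORDER[drug_class], strength)


@dataclass
class PathwayEntry:
    """First-line versus add-on products for one episode."""

    ordinal: int
    first_line: list[tuple[str, str]]
    add_on: list[tuple[str, str]]


def pathway_decompose(episode: Episode) -> PathwayEntry:
    """Split an episode's products by whether they were present at start.

    First-line products have an issue on the episode's start date (for
    episode 1 this includes the merged pre-index window, i.e. any issue on
    or before the index date).  Add-on products first appear later; they
    are ordered by first-issue date, then canonical product order.
    """
    first_issue: dict[tuple[str, str], "dt.date"] = {}
    for event in episode.events:  # events are date-sorted
        product = (event.drug_class, event.strength_label)
        if product not in first_issue:
            first_issue[product] = event.date

    first_line = sorted(
        (p for p, d in first_issue.items() if d <= episode.start_date),
        key=_product_key,
    )
    add_on = sorted(
        (p for p, d in first_issue.items() if d > episode.start_date),
        key=lambda p: (first_issue[p], _product_key(p)),
    )
    return PathwayEntry(ordinal=episode.ordinal, first_line=first_line, add_on=add_on)


@dataclass
class PathwayRecord:
    patient_id: str
    entries: list[PathwayEntry]


def decompose_patient(patient_id: str, episodes: list[Episode]) -> PathwayRecord:
    return PathwayRecord(
        patient_id=patient_id, entries=[pathway_decompose(e) for e in episodes]
    )


def _render_products(products: list[tuple[str, str]], *, canonical: bool) -> str:
    if not products:
        return ""
    ordered = sorted(products, key=_product_key) if canonical else products
    return " & ".join(product_display(c, s) for c, s in ordered)


def pathway_signature(record: PathwayRecord, max_episodes: int = 3) -> str:
    """Canonical pipe-delimited pathway key over the first few episodes.

    Per observed episode the segment pair is ``first-line|add-on`` with
    products in canonical (class, strength) order; missing episodes render
    as ``None|None``, and an empty add-on set of an observed episode as an
    empty segment.  Two patients with the same clinical pathway — whatever
    the input row order — get identical keys.
    """
    segments: list[str] = []
    for ordinal in range(1, max_episodes + 1):
        entry = next((e for e in record.entries if e.ordinal == ordinal), None)
        if entry is None:
            segments += ["None", "None"]
        else:
            segments.append(_render_products(entry.first_line, canonical=True))
            segments.append(_render_products(entry.add_on, canonical=True))
    return "|".join(segments)


@dataclass
class ClassifiedEpisode:
    """An episode together with its regimen category and pathway entry."""

    patient_id: str
    ordinal: int
    start_year: int
    category: str
    pathway: PathwayEntry


def classify_patient(patient_id: str, episodes: list[Episode]) -> list[ClassifiedEpisode]:
    return [
        ClassifiedEpisode(
            patient_id=patient_id,
            ordinal=e.ordinal,
            start_year=e.start_year,
            category=classify_episode(e.class_set),
            pathway=pathway_decompose(e),
        )
        for e in episodes
    ]


def combination_percentage(patch_only_count: int, total: int) -> float:
    """Share of episodes that are combination (not patch-only), 1 decimal."""
    return percent(total - patch_only_count, total, 1)
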