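"""Grouping NRT prescriptions into treatment episodes.

An episode is a maximal chronological run of NRT prescriptions in which
consecutive issue dates are at most 90 days apart; a gap greater than 90
days starts a new episode, so the smallest possible gap between episodes
is 91 days.  Episode 1 is anchored at the index date; non-patch events in
the two weeks before index (permitted by the cohort rules as the possible
start of combination therapy) are merged into episode 1 without moving
its start date.

Gaps are measured issue date to issue date.  Prescription duration is not
modelled — the schema carries no quantity or days-supply field — so an
episode ends on its last issue date, and a patient is considered to have
discontinued prescribed NRT when more than 90 days separate that date
from the end of follow-up.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

from .records import PrescriptionEvent

#: Maximum within-episode gap, days; a larger gap starts a new episode.
GAP_THRESHOLD_DAYS = 90
#: Pre-index window merged into episode 1, days.
PRE_INDEX_WINDOW_DAYS = 14


@dataclass
class Episode:
    """One ordinal-numbered block of NRT prescriptions."""

    patient_id: str
    ordinal: int
    start_date: dt.date
    end_date: dt.date
    events: list[PrescriptionEvent]

    @property
    def product_set(self) -> frozenset[tuple[str, str]]:
        """Deduplicated (drug_class, strength_label) pairs."""
        return frozenset((e.drug_class, e.strength_label) for e in self.events)

    @property
    def class_set(self) -> frozenset[str]:
        return frozenset(e.drug_class for e in self.events)

    @property
    def start_year(self) -> int:
        return self.start_date.year


@dataclass(frozen=True)
class DiscontinuationStatus:
    patient_id: str
    discontinued: bool
    last_episode_end: dt.date
    followup_end: dt.date


def build_episodes(
    nrt_events: list[PrescriptionEvent],
    index_date: dt.date,
    *,
    gap_threshold: int = GAP_THRESHOLD_DAYS,
    pre_index_window: int = PRE_INDEX_WINDOW_DAYS,
) -> list[Episode]:
    """Partition one patient's NRT events into ordered episodes.

    ``nrt_events`` must be this patient's NRT-class events (bupropion and
    varenicline never enter episodes), sorted by date, none earlier than
    ``index_date - pre_index_window``.  Episode 1's start date is the
    index date even when merged pre-index events precede it.
    """
    if not nrt_events:
        raise ValueError("an included patient has at least one patch event")
    if any(not e.is_nrt for e in nrt_events):
        raise ValueError("only NRT-class events enter episodes")
    if any(e.date < index_date - dt.timedelta(days=pre_index_window) for e in nrt_events):
        raise ValueError("event precedes the allowed pre-index window")
    if any(a.date > b.date for a, b in zip(nrt_events, nrt_events[1:])):
        raise ValueError("events must be sorted by date")

    episodes: list[Episode] = []
    current: list[PrescriptionEvent] = [nrt_events[0]]
    for event in nrt_events[1:]:
        if (event.date - current[-1].date).days > gap_threshold:
            episodes.append(_finish(current, len(episodes) + 1, index_date))
            current = [event]
        else:
            current.append(event)
    episodes.append(_finish(current, len(episodes) + 1, index_date))
    return episodes


def _finish(events: list[PrescriptionEvent], ordinal: int, index_date: dt.date) -> Episode:
    # Pre-index merged events widen episode 1's product set but never move
    # its anchor: follow-up is measured from the index patch.
    start = index_date if ordinal == 1 else events[0].date
    return Episode(
        patient_id=events[0].patient_id,
        ordinal=ordinal,
        start_date=start,
        end_date=events[-1].date,
        events=list(events),
    )


def initial_nrt(episode: Episode) -> frozenset[tuple[str, str]]:
    """All products and strengths of the first episode (the "initial NRT")."""
    if episode.ordinal != 1:
        raise ValueError("initial NRT is defined on episode 1")
    return episode.product_set


def discontinuation(
    episodes: list[Episode],
    followup_end: dt.date,
    *,
    gap_threshold: int = GAP_THRESHOLD_DAYS,
) -> DiscontinuationStatus:
    """Discontinued iff the last episode ends >90 days before follow-up end.

    A last episode ending within the final 90 days of follow-up — or on or
    after its end — means the patient was still receiving prescribed NRT
    when observation stopped.
    """
    if not episodes:
        raise ValueError("discontinuation requires at least one episode")
    last_end = episodes[-1].end_date
    return DiscontinuationStatus(
        patient_id=episodes[-1].patient_id,
        discontinued=(followup_end - last_end).days > gap_threshold,
        last_episode_end=last_end,
        followup_end=followup_end,
    )


def inter_episode_gaps(episodes: list[Episode]) -> list[int]:
    """Day counts from each episode's end to the next episode's start."""
    return [
        (nxt.start_date - cur.end_date).days
        for cur, nxt in zip(episodes, episodes[1:])
    ]


def trim_to_followup(
    nrt_events: list[PrescriptionEvent], followup_end: dt.date
) -> list[PrescriptionEvent]:
    """Drop events after the end of follow-up (with a warning).

    Follow-up defines the observation boundary; an issue recorded after
    the practice's last collection or the patient's transfer-out cannot be
    part of the observed treatment course.
    """
    kept = [e for e in nrt_events if e.date <= followup_end]
    if len(kept) < len(nrt_events):
        warnings.warn(
            f"patient {nrt_events[0].patient_id}: dropped "
            f"{len(nrt_events) - len(kept)} event(s) after follow-up end",
            stacklevel=2,
        )
    return kept
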