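"""Episode construction under the 90-day gap rule."""

import datetime as dt

import numpy as np
import pytest

from nrt_pathways.episodes import (
    build_episodes,
    discontinuation,
    initial_nrt,
    inter_episode_gaps,
    trim_to_followup,
)
from nrt_pathways.records import PrescriptionEvent

D = dt.date
INDEX = D(2009, 3, 1)


def rx(date, drug_class="NRT_patch", strength="21 mg/24 hours"):
    return PrescriptionEvent("p1", date, drug_class, strength)


def days(*offsets):
    """Patch events at the given day offsets from the index date."""
    return [rx(INDEX + dt.timedelta(days=o)) for o in sorted(offsets)]


def brute_force_partition(dates: list[dt.date], threshold: int = 90) -> list[list[dt.date]]:
    """Independent oracle: break after every gap > threshold, take maximal runs."""
    runs: list[list[dt.date]] = [[dates[0]]]
    for prev, cur in zip(dates, dates[1:]):
        if (cur - prev).days > threshold:
            runs.append([cur])
        else:
            runs[-1].append(cur)
    return runs


class TestGapRule:
    def test_gap_of_90_days_stays_one_episode(self):
        episodes = build_episodes(days(0, 90), INDEX)
        assert len(episodes) == 1
        assert episodes[0].start_date == INDEX
        assert episodes[0].end_date == INDEX + dt.timedelta(days=90)

    def test_gap_of_91_days_splits(self):
        episodes = build_episodes(days(0, 91), INDEX)
        assert [e.start_date for e in episodes] == [INDEX, INDEX + dt.timedelta(days=91)]
        assert [e.ordinal for e in episodes] == [1, 2]

    def test_oracle_equivalence_on_random_inputs(self):
        rng = np.random.default_rng(1729)
        for _ in range(1000):
            n = int(rng.integers(1, 26))
            gaps = rng.integers(1, 401, size=n - 1)
            dates = [INDEX]
            for g in gaps:
                dates.append(dates[-1] + dt.timedelta(days=int(g)))
            events = [rx(d) for d in dates]
            episodes = build_episodes(events, INDEX)
            oracle = brute_force_partition(dates)
            assert [[e.date for e in ep.events] for ep in episodes] == oracle

    def test_idempotence(self):
        rng = np.random.default_rng(7)
        offsets = np.cumsum(rng.integers(1, 200, size=15))
        episodes = build_episodes(days(0, *offsets.tolist()), INDEX)
        flattened = [e for ep in episodes for e in ep.events]
        rebuilt = build_episodes(flattened, INDEX)
        assert [[e.date for e in ep.events] for ep in rebuilt] == [
            [e.date for e in ep.events] for ep in episodes
        ]

    def test_episode_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            offsets = np.cumsum(rng.integers(1, 250, size=12)).tolist()
            events = days(0, *offsets)
            n90 = len(build_episodes(events, INDEX, gap_threshold=90))
            n120 = len(build_episodes(events, INDEX, gap_threshold=120))
            assert n120 <= n90

    def test_preindex_nonpatch_merged_but_start_anchored(self):
        events = sorted(
            [rx(INDEX - dt.timedelta(days=9), "NRT_inhalator", "10 mg"), rx(INDEX)],
            key=lambda e: e.date,
        )
        episodes = build_episodes(events, INDEX)
        assert len(episodes) == 1
        assert episodes[0].start_date == INDEX
        assert episodes[0].class_set == {"NRT_patch", "NRT_inhalator"}

    def test_contract_violations_raise(self):
        with pytest.raises(ValueError):
            build_episodes([], INDEX)
        with pytest.raises(ValueError):
            build_episodes([rx(INDEX), rx(INDEX - dt.timedelta(days=30))], INDEX)
        with pytest.raises(ValueError):
            build_episodes([rx(INDEX - dt.timedelta(days=15))], INDEX)
        with pytest.raises(ValueError):
            build_episodes(
                [PrescriptionEvent("p1", INDEX, "varenicline", "")], INDEX
            )


class TestInitialNrt:
    def test_combination_products_collected(self):
        events = [rx(INDEX), rx(INDEX + dt.timedelta(days=7), "NRT_inhalator", "10 mg")]
        (episode,) = build_episodes(events, INDEX)
        assert initial_nrt(episode) == {
            ("NRT_patch", "21 mg/24 hours"),
            ("NRT_inhalator", "10 mg"),
        }

    def test_same_day_duplicates_deduplicate(self):
        (episode,) = build_episodes([rx(INDEX), rx(INDEX)], INDEX)
        assert initial_nrt(episode) == {("NRT_patch", "21 mg/24 hours")}

    def test_multiple_patch_strengths_all_counted(self):
        events = [
            rx(INDEX),
            rx(INDEX + dt.timedelta(days=60), "NRT_patch", "14 mg/24 hours"),
            rx(INDEX + dt.timedelta(days=80), "NRT_patch", "7 mg/24 hours"),
        ]
        (episode,) = build_episodes(events, INDEX)
        assert len(initial_nrt(episode)) == 3

    def test_only_defined_for_first_episode(self):
        _, second = build_episodes(days(0, 100), INDEX)
        with pytest.raises(ValueError):
            initial_nrt(second)


class TestDiscontinuation:
    def test_91_days_quiet_means_discontinued(self):
        episodes = build_episodes(days(0), INDEX)
        status = discontinuation(episodes, INDEX + dt.timedelta(days=91))
        assert status.discontinued

    def test_90_days_quiet_still_on_treatment(self):
        episodes = build_episodes(days(0), INDEX)
        status = discontinuation(episodes, INDEX + dt.timedelta(days=90))
        assert not status.discontinued

    def test_last_issue_on_or_after_followup_end_not_discontinued(self):
        episodes = build_episodes(days(0), INDEX)
        assert not discontinuation(episodes, INDEX).discontinued


class TestInterEpisodeGaps:
    def test_minimum_gap_is_91(self):
        episodes = build_episodes(days(0, 91), INDEX)
        assert inter_episode_gaps(episodes) == [91]

    def test_three_episodes_two_gaps(self):
        episodes = build_episodes(days(0, 100, 300), INDEX)
        assert len(episodes) == 3
        assert inter_episode_gaps(episodes) == [100, 200]

    def test_single_episode_empty(self):
        assert inter_episode_gaps(build_episodes(days(0), INDEX)) == []


def test_trim_drops_events_after_followup_with_warning():
    events = days(0, 30, 200)
    with pytest.warns(UserWarning, match="dropped 1"):
        kept = trim_to_followup(events, INDEX + dt.timedelta(days=100))
    assert len(kept) == 2
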