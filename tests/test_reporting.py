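"""Summary tables, headline arithmetic and descriptive statistics."""

import dataclasses
import datetime as dt

import pytest

from nrt_pathways.pipeline import run_pipeline
from nrt_pathways.records import Dataset, PatientRecord, PracticeRecord, PrescriptionEvent
from nrt_pathways.reporting import (
    RegimenByYearTable,
    combination_breakdown,
    combination_share,
    pooled_repeat_proportion,
    repeat_episode_rate,
    summarize_values,
    top_pathways,
)
from nrt_pathways.rounding import percent, round_half_up
from nrt_pathways.synth import ExclusionKnobs, SynthConfig, generate

D = dt.date


def one_patient_dataset() -> Dataset:
    practice = PracticeRecord("pr1", D(2000, 1, 1), D(2001, 1, 1), D(2013, 6, 30))
    patient = PatientRecord(
        "p1", "pr1", 1970, "male", registration_date=D(2005, 1, 1), townsend_quintile=2
    )
    events = [PrescriptionEvent("p1", D(2009, 6, 1), "NRT_patch", "21 mg/24 hours")]
    return Dataset({"pr1": practice}, {"p1": patient}, events)


class TestRounding:
    def test_half_up_not_bankers(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(74.255, 2) == 74.26

    def test_percent_handles_empty_denominator(self):
        assert percent(5, 0) == 0.0


class TestRegimenByYear:
    def test_forced_patch_only_config_yields_pure_monotherapy(self):
        config = dataclasses.replace(
            SynthConfig(n_patients=500),
            p_combination_by_year=(0.0, 0.0, 0.0, 0.0),
            p_nonpatch_only=0.0,
            exclusion_knobs=ExclusionKnobs(0.0, 0.0, 0.0, 0.0, 0.0),
        )
        result = run_pipeline(generate(config, 11))
        table = result.tables[1]
        assert result.attrition["study_population"].count == 500
        for column in table.columns:
            assert table.pct("patch_only", column) == 100.0
            assert combination_share(table, column) == 0.0

    def test_one_patient_dataset_single_full_cell(self):
        result = run_pipeline(one_patient_dataset())
        table = result.tables[1]
        assert table.count("patch_only", "overall") == 1
        assert table.pct("patch_only", "2009") == 100.0

    def test_column_conservation(self, default_result):
        for table in default_result.tables.values():
            for column in table.columns:
                n = table.n(column)
                if n == 0:
                    continue
                counts = sum(table.count(c, column) for c in table.categories)
                pcts = sum(table.pct(c, column) for c in table.categories)
                assert counts == n
                assert pcts == pytest.approx(100.0, abs=0.05)

    def test_missing_column_lookup_errors(self, default_result):
        with pytest.raises(KeyError):
            combination_share(default_result.tables[1], "1999")

    def test_later_ordinals_may_start_after_window(self, default_result):
        years = [int(c) for c in default_result.tables[2].columns if c != "overall"]
        assert max(years) >= 2012  # repeat episodes run past the index window


class TestCombinationArithmetic:
    def test_breakdown_of_single_combination_episode(self):
        table = RegimenByYearTable.from_counts(
            1, {"overall": {"patch_only": 9, "patch_gum": 1}}
        )
        assert combination_breakdown(table, "overall") == {"patch_gum": 100.0}

    def test_zero_combination_episodes_empty_mapping(self):
        table = RegimenByYearTable.from_counts(1, {"overall": {"patch_only": 5}})
        assert combination_breakdown(table, "overall") == {}

    def test_share_plus_patch_only_share_complement(self, default_result):
        table = default_result.tables[1]
        for column in table.columns:
            share = combination_share(table, column)
            patch_exact = 100.0 * table.count("patch_only", column) / table.n(column)
            assert share == pytest.approx(100.0 - patch_exact, abs=0.05)


class TestTopPathways:
    def test_majority_signature_ranked_first_with_share(self):
        signatures = ["A"] * 3 + ["B", "C", "D", "E", "F", "G", "H"]
        ranked = top_pathways(signatures, k=10)
        assert ranked[0].signature == "A"
        assert ranked[0].count == 3
        assert ranked[0].pct == 30.0

    def test_k_beyond_distinct_returns_all(self):
        ranked = top_pathways(["A", "B"], k=10)
        assert len(ranked) == 2

    def test_equal_counts_tie_broken_lexicographically(self):
        ranked = top_pathways(["B", "A", "A", "B"], k=2)
        assert [r.signature for r in ranked] == ["A", "B"]


class TestSummarizeValues:
    def test_three_point_sample(self):
        stats = summarize_values([18, 42, 96])
        assert stats["min"] == 18 and stats["max"] == 96 and stats["median"] == 42

    def test_quartiles_linear_interpolation(self):
        stats = summarize_values([1, 2, 3, 4])
        assert stats["q1"] == 1.75
        assert stats["q3"] == 3.25
        assert stats["median"] == 2.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize_values([])


class TestHeadlineStats:
    def test_no_repeats_no_history_gives_zero_pooled(self):
        result = run_pipeline(one_patient_dataset())
        assert result.headline["pct_second_episode"] == 0.0
        assert result.headline["pct_pooled_repeat"] == 0.0

    def test_headline_recomputable_from_own_counts(self, default_result):
        h = default_result.headline
        assert h["pct_second_episode"] == repeat_episode_rate(
            h["n_with_second_episode"], h["n_included"]
        )
        assert h["pct_pooled_repeat"] == pooled_repeat_proportion(
            h["n_with_second_episode"], h["n_excluded_prior_nrt"], h["n_patch_cohort"]
        )
        assert h["pct_prior_bup_var"] == percent(
            h["n_prior_bup_var"], h["n_nrt_cohort"], 1
        )

    def test_all_observed_gaps_exceed_90_days(self, default_result):
        gaps = default_result.headline.get("inter_episode_gap_days")
        assert gaps is not None
        assert gaps["min"] >= 91


class TestBaselineSummary:
    def test_group_sizes_partition_included(self, default_result):
        groups = default_result.baseline.groups
        overall = groups["overall"]["n"]
        assert overall == default_result.headline["n_included"]
        assert sum(s["n"] for g, s in groups.items() if g != "overall") == overall

    def test_gender_counts_sum_to_group_n(self, default_result):
        for summary in default_result.baseline.groups.values():
            male = summary["gender"]["male"][0]
            female = summary["gender"]["female"][0]
            assert male + female == summary["n"]
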