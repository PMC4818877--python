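"""Prefilter, pair evaluation and the greedy clean-up loop."""

import numpy as np
import pytest

from barclean import (
    CleanupParams,
    clean_lane,
    evaluate_pair,
    levenshtein,
    prefilter,
    read_threshold_filter,
)
from barclean.cleanup import CONTAINS_N, LOW_READS

from conftest import make_table


class TestPrefilter:
    def test_read_cutoff_and_n_exclusion(self):
        table = make_table({
            "AAAAAAAAAAAAAAA": [50, 49],        # 99 reads: below cutoff
            "CCCCCCCCCCCCCCC": [50, 50],        # exactly 100: kept
            "ACGTNCGTACGTACG": [500_000, 500_000],  # N: excluded despite reads
        })
        kept, removed = prefilter(table, CleanupParams())
        assert kept.barcodes == ["CCCCCCCCCCCCCCC"]
        assert ("AAAAAAAAAAAAAAA", LOW_READS) in removed
        assert ("ACGTNCGTACGTACG", CONTAINS_N) in removed

    def test_partition_is_complete(self, default_lane):
        table, _ = default_lane
        kept, removed = prefilter(table)
        assert set(kept.barcodes) | {b for b, _ in removed} == set(table.barcodes)
        assert not set(kept.barcodes) & {b for b, _ in removed}


MOTHER = "ACGTACGTACGTACG"
DAUGHTER1 = "ACGTACGTACGTACC"          # one substitution
FAR = "TGCATGCATGCATGC"                # unrelated


class TestEvaluatePair:
    def test_distance_failure_short_circuits(self):
        ev = evaluate_pair([10_000] * 3, [10] * 3, MOTHER, FAR)
        assert ev.verdict == "not-daughter"
        assert ev.reason == "distance"
        assert ev.score is None
        assert ev.distance == levenshtein(MOTHER, FAR)

    def test_ratio_failure(self):
        ev = evaluate_pair([1000] * 3, [100] * 3, MOTHER, DAUGHTER1)
        assert ev.verdict == "not-daughter"
        assert ev.reason == "ratio"
        assert ev.score.ratio == pytest.approx(0.1)

    def test_score_undefined_failure(self):
        params = CleanupParams()
        ev = evaluate_pair([150, 180], [1, 2], MOTHER, DAUGHTER1, params)
        assert ev.reason == "score-undefined"

    def test_predictable_daughter_is_accepted(self):
        mother = [100_000, 200_000, 300_000]
        daughter = [100, 200, 300]  # exactly 0.001 of the mother everywhere
        ev = evaluate_pair(mother, daughter, MOTHER, DAUGHTER1)
        assert ev.verdict == "daughter"
        assert ev.reason is None
        assert ev.score.loglik > -2 * np.log10(600) - 1

    def test_erratic_daughter_is_rejected_on_score(self):
        mother = [100_000, 100_000, 100_000]
        daughter = [600, 0, 0]  # same totals, maximally uneven
        ev = evaluate_pair(mother, daughter, MOTHER, DAUGHTER1)
        assert ev.reason == "score-below-threshold"

    def test_caller_must_order_by_prevalence(self):
        with pytest.raises(ValueError):
            evaluate_pair([10, 10], [100, 100], MOTHER, DAUGHTER1)


GRANDMOTHER = "AAAAAAAAAAAAAAA"
CHILD = "CAAAAAAAAAAAAAA"           # d(GM, C) = 1
GRANDCHILD = "CGAAAAAAAAAAAAA"      # d(GM, GC) = 2
GRANDCHILD_FAR = "CGTGCAAAAAAAAAA"  # d(GM, .) = 5, d(C, .) = 4


def _family_rows(grandchild):
    m = [100_000_000] * 4
    d = [100_000] * 4          # 0.001 of the mother, constant
    g = [100] * 4              # 0.001 of the daughter
    return {GRANDMOTHER: m, CHILD: d, grandchild: g}


class TestCleanLane:
    def test_single_barcode_is_retained(self):
        table = make_table({MOTHER: [200, 300]})
        result = clean_lane(table)
        assert result.retained == [MOTHER]
        assert not result.removed_as_daughter

    def test_distant_abundant_barcodes_both_survive(self):
        table = make_table({MOTHER: [10_000] * 4, FAR: [9_000] * 4})
        result = clean_lane(table)
        assert set(result.retained) == {MOTHER, FAR}

    def test_granddaughter_matching_mother_criteria_is_removed(self):
        result = clean_lane(make_table(_family_rows(GRANDCHILD)))
        assert result.retained == [GRANDMOTHER]
        removed = {ev.daughter: ev.mother for ev in result.removed_as_daughter}
        # the daughter is claimed by the mother; the grandchild, never seeing
        # its removed parent as a candidate mother, is claimed transitively
        assert removed == {CHILD: GRANDMOTHER, GRANDCHILD: GRANDMOTHER}

    def test_granddaughter_outside_mother_reach_survives(self):
        result = clean_lane(make_table(_family_rows(GRANDCHILD_FAR)))
        assert set(result.retained) == {GRANDMOTHER, GRANDCHILD_FAR}

    def test_deterministic_and_row_order_independent(self, default_lane):
        table, _ = default_lane
        result_a = clean_lane(table)
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_barcodes)
        shuffled = table.counts.iloc[perm]
        from barclean import ReadCountTable

        result_b = clean_lane(ReadCountTable(shuffled, table.samples))
        assert result_a.retained == result_b.retained
        assert [ev.daughter for ev in result_a.removed_as_daughter] == [
            ev.daughter for ev in result_b.removed_as_daughter
        ]

    def test_result_partitions_input(self, default_lane):
        table, _ = default_lane
        result = clean_lane(table)
        parts = [
            set(result.retained),
            set(result.removed_daughter_sequences),
            {b for b, _ in result.removed_by_prefilter},
        ]
        assert set.union(*parts) == set(table.barcodes)
        assert sum(len(p) for p in parts) == table.n_barcodes

    def test_retained_counts_are_untouched(self, default_lane):
        table, _ = default_lane
        result = clean_lane(table)
        sub = table.subset_barcodes(result.retained)
        assert (sub.counts == table.counts.loc[sub.barcodes]).all().all()

    def test_no_retained_pair_is_in_the_acceptance_region(self, default_lane):
        table, _ = default_lane
        params = CleanupParams()
        result = clean_lane(table, params)
        sub = table.subset_barcodes(result.retained)
        totals = sub.totals().to_numpy()
        order = np.argsort(-totals, kind="stable")
        counts = sub.matrix()[order]
        seqs = [sub.barcodes[i] for i in order]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                ev = evaluate_pair(counts[i], counts[j], seqs[i], seqs[j], params)
                assert ev.verdict == "not-daughter"

    def test_multi_lane_table_is_rejected(self):
        table_a = make_table({MOTHER: [100, 100]}, lane_id="lane1")
        from barclean import ReadCountTable, SampleMeta
        import pandas as pd

        samples = [SampleMeta("s0", "lane1"), SampleMeta("s1", "lane2")]
        frame = pd.DataFrame({"s0": [100], "s1": [100]}, index=[MOTHER])
        with pytest.raises(ValueError):
            clean_lane(ReadCountTable(frame, samples))
        assert clean_lane(table_a)  # single lane is fine


class TestReadThresholdFilter:
    def test_boundaries(self):
        table = make_table({
            "A" * 15: [99, 0],
            "C" * 15: [50, 50],
            "G" * 15: [100, 1],
        })
        assert len(read_threshold_filter(table, 1)) == 3
        assert set(read_threshold_filter(table, 100)) == {"C" * 15, "G" * 15}
        with pytest.raises(ValueError):
            read_threshold_filter(table, 0)
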