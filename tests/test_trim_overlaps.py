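"""Overlap resolution by cumulative-score maximization."""

import numpy as np
import pytest

from pafkit import (
    OverlapPair,
    ScoreScheme,
    best_split,
    find_query_overlaps,
    trim_paf,
)
from pafkit.fixtures import SvSpec, random_alignment, simulate_alignment
from pafkit.trim_overlaps import split_total_score

from conftest import brute_best_split, make_rec

SCHEME = ScoreScheme()


def two_overlapping(cg_a="60=", cg_b="60="):
    a = make_rec(cg_a, 100, 0, 60, "+", 300, 0, 60)
    b = make_rec(cg_b, 100, 40, 100, "+", 300, 100, 160)
    return a, b


class TestFindOverlaps:
    def test_single_pair(self):
        a, b = two_overlapping()
        (pair,) = find_query_overlaps([a, b])
        assert (pair.olo, pair.ohi) == (40, 60)
        assert pair.left is a and pair.right is b

    def test_disjoint_spans_give_nothing(self):
        a = make_rec("40=", 100, 0, 40, "+", 300, 0, 40)
        b = make_rec("40=", 100, 60, 100, "+", 300, 100, 140)
        assert find_query_overlaps([a, b]) == []

    def test_different_query_names_never_pair(self):
        a, b = two_overlapping()
        b.qname = "other"
        assert find_query_overlaps([a, b]) == []

    def test_three_mutual_overlaps_sorted_largest_first(self):
        # brute force: all C(3,2) pairs, ordered by overlap length
        a = make_rec("60=", 100, 0, 60, "+", 300, 0, 60)
        b = make_rec("60=", 100, 30, 90, "+", 300, 100, 160)
        c = make_rec("50=", 100, 50, 100, "+", 300, 200, 250)
        pairs = find_query_overlaps([a, b, c])
        spans = [(p.olo, p.ohi) for p in pairs]
        assert len(pairs) == 3
        assert spans == sorted(spans, key=lambda s: -(s[1] - s[0]))
        assert (pairs[0].olo, pairs[0].ohi) == (50, 90)  # b/c overlap is largest


class TestBestSplit:
    def test_all_ties_pick_leftmost(self):
        a, b = two_overlapping()
        (pair,) = find_query_overlaps([a, b])
        # brute force over all 21 split points: constant total, leftmost wins
        p_star, best = brute_best_split(a, b, 40, 60, SCHEME)
        assert p_star == 40
        assert best_split(pair, SCHEME) == 40
        assert split_total_score(pair, 40, SCHEME) == best

    def test_left_mismatches_beyond_50(self):
        a, b = two_overlapping(cg_a="50=10X")
        (pair,) = find_query_overlaps([a, b])
        p_star, _ = brute_best_split(a, b, 40, 60, SCHEME)
        assert p_star == 40
        assert best_split(pair, SCHEME) == 40

    def test_crossover_at_quality_switch(self):
        # left perfect in [40,50) and mismatching in [50,60); right the mirror
        a = make_rec("50=10X", 100, 0, 60, "+", 300, 0, 60)
        b = make_rec("10X50=", 100, 40, 100, "+", 300, 100, 160)
        (pair,) = find_query_overlaps([a, b])
        p_star, _ = brute_best_split(a, b, 40, 60, SCHEME)
        assert p_star == 50
        assert best_split(pair, SCHEME) == 50

    def test_split_matches_brute_force_on_random_fixtures(self):
        checked = 0
        for seed in range(12):
            sim = random_alignment(
                seed,
                target_len=4000,
                weights={"TANDEM_DUP": 0.5, "SUBST_RATE": 0.3, "DELETION": 0.2},
                max_indel=200,
                dup_len=(50, 250),
            )
            for pair in find_query_overlaps(sim.records):
                if pair.length > 500:
                    continue
                p_star, best = brute_best_split(
                    pair.left, pair.right, pair.olo, pair.ohi, SCHEME
                )
                got = best_split(pair, SCHEME)
                assert got == p_star
                assert split_total_score(pair, got, SCHEME) == pytest.approx(best)
                checked += 1
        assert checked >= 5


def _assert_disjoint(records):
    by_query = {}
    for rec in records:
        by_query.setdefault(rec.qname, []).append((rec.qstart, rec.qend))
    for spans in by_query.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2, f"overlap between {(s1, e1)} and {(s2, e2)}"


class TestTrimPaf:
    def test_two_record_resolution(self):
        a, b = two_overlapping()
        out = trim_paf([a, b])
        assert [(r.qstart, r.qend) for r in out] == [(0, 40), (40, 100)]
        _assert_disjoint(out)

    def test_non_overlapping_input_is_fixed_point(self):
        a = make_rec("40=", 100, 0, 40, "+", 300, 0, 40)
        b = make_rec("40=", 100, 60, 100, "+", 300, 100, 140)
        assert trim_paf([a, b]) == [a, b]

    def test_containment_resolved_or_dropped(self):
        # B strictly inside A; enumerating two-split resolutions on this toy
        # shows the optimum keeps every base of A (possibly as two pieces)
        # and drops the all-mismatch B entirely.
        a = make_rec("200=", 200, 0, 200, "+", 400, 0, 200)
        b = make_rec("50X", 200, 80, 130, "+", 400, 300, 350)
        out = trim_paf([a, b])
        _assert_disjoint(out)
        assert all(r.tname == "t" and r.tstart < 200 for r in out)  # all from A
        covered = sorted((r.qstart, r.qend) for r in out)
        assert covered[0][0] == 0 and covered[-1][1] == 200
        assert sum(e - s for s, e in covered) == 200  # no base of A lost

    def test_containment_with_better_inner_record(self):
        a = make_rec("80=50X70=", 200, 0, 200, "+", 400, 0, 200)
        b = make_rec("50=", 200, 80, 130, "+", 400, 300, 350)
        out = trim_paf([a, b])
        _assert_disjoint(out)
        # the mismatching stretch of A is ceded to B
        assert len(out) == 3 or len(out) == 2

    def test_idempotent(self):
        a, b = two_overlapping("50=10X")
        once = trim_paf([a, b])
        assert trim_paf(once) == once

    def test_no_query_base_multiply_aligned_on_duplication_fixtures(self):
        for seed in range(8):
            sim = random_alignment(
                seed,
                target_len=6000,
                weights={"TANDEM_DUP": 0.6, "INVERSION": 0.2, "SUBST_RATE": 0.2},
            )
            out = trim_paf(sim.records)
            _assert_disjoint(out)
            for rec in out:
                rec.validate()
                assert rec.qstart >= 0 and rec.qend <= sim.query_len
            assert trim_paf(out) == out  # idempotence

    def test_retained_pairs_all_in_truth_map(self):
        from pafkit import aligned_columns

        sim = simulate_alignment(
            4000, [SvSpec("TANDEM_DUP", 1000, 200)], seed=13
        )
        out = trim_paf(sim.records)
        _assert_disjoint(out)
        truth = sim.truth.pairs()
        for rec in out:
            for col in aligned_columns(rec):
                if col.kind in "=X":
                    assert (col.tpos, col.qpos, rec.strand) in truth

    def test_strand_mixed_overlap(self):
        a = make_rec("60=", 100, 0, 60, "+", 300, 0, 60)
        b = make_rec("60=", 100, 40, 100, "-", 300, 100, 160)
        out = trim_paf([a, b])
        _assert_disjoint(out)
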