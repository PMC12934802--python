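"""Coordinate arithmetic: column expansion, sub-alignments, flip, invert."""

import numpy as np
import pytest

from pafkit import (
    GAP,
    aligned_columns,
    count_events,
    CigarError,
    CigarString,
    flip_query_orientation,
    invert_record,
    subalignment_by_query,
    subalignment_by_target,
)
from pafkit.fixtures import random_alignment

from conftest import (
    assert_matches_brute,
    brute_columns,
    brute_subalignment,
    expand_kinds,
    make_rec,
)


class TestAlignedColumns:
    def test_forward_identity(self):
        rec = make_rec("3=", 3, 0, 3, "+", 20, 10, 13)
        assert [(c.tpos, c.qpos) for c in aligned_columns(rec)] == [
            (10, 0),
            (11, 1),
            (12, 2),
        ]

    def test_reverse_strand_descends_in_query(self):
        # oracle: on a 3-bp toy, reverse-complement base i of the query
        # pairs with target base 2-i, i.e. qpos = qend-1 ... qstart
        rec = make_rec("3=", 3, 0, 3, "-", 20, 10, 13)
        assert [(c.tpos, c.qpos) for c in aligned_columns(rec)] == [
            (10, 2),
            (11, 1),
            (12, 0),
        ]

    def test_deletion_gap_column(self):
        rec = make_rec("1=1D1=", 2, 0, 2, "+", 3, 0, 3)
        assert [(c.tpos, c.qpos, c.kind) for c in aligned_columns(rec)] == [
            (0, 0, "="),
            (1, GAP, "D"),
            (2, 1, "="),
        ]

    def test_missing_cigar_is_error(self):
        rec = make_rec("3=", 3, 0, 3, "+", 20, 10, 13)
        rec.cigar = None
        with pytest.raises(CigarError):
            list(aligned_columns(rec))

    def test_agrees_with_per_base_oracle_on_generated_records(self):
        for seed in range(3):
            for rec in random_alignment(seed, target_len=4000).records:
                assert [tuple(c) for c in aligned_columns(rec)] == brute_columns(rec)


class TestCountEvents:
    @pytest.mark.parametrize(
        "cg,expected",
        [
            ("90=10X", (90, 10, 0, 0, 0, 0)),
            ("10=2I5=3D1X", (15, 1, 1, 1, 2, 3)),  # per-op tally oracle
            ("", (0, 0, 0, 0, 0, 0)),
        ],
    )
    def test_tallies(self, cg, expected):
        c = count_events(CigarString.parse(cg))
        assert (
            c.matches,
            c.mismatches,
            c.ins_events,
            c.del_events,
            c.ins_bases,
            c.del_bases,
        ) == expected

    def test_ambiguous_m_rejected_with_eqx_advice(self):
        with pytest.raises(CigarError, match="eqx"):
            count_events(CigarString.parse("10M"))


class TestSubalignmentByTarget:
    def test_identity_window(self, identity_record):
        sub = subalignment_by_target(identity_record, 10, 20)
        assert (sub.tstart, sub.tend, sub.qstart, sub.qend) == (10, 20, 10, 20)
        assert str(sub.cigar) == "10="

    def test_window_straddles_deletion(self):
        rec = make_rec("50=10D50=", 100, 0, 100, "+", 110, 0, 110)
        sub = subalignment_by_target(rec, 45, 65)
        assert str(sub.cigar) == "5=10D5="
        assert (sub.tstart, sub.tend, sub.qstart, sub.qend) == (45, 65, 45, 55)
        assert_matches_brute(sub, brute_subalignment(rec, 45, 65, "target"))

    def test_reverse_strand_window(self):
        rec = make_rec("100=", 100, 0, 100, "-", 100, 0, 100)
        sub = subalignment_by_target(rec, 10, 20)
        assert (sub.qstart, sub.qend, sub.strand) == (80, 90, "-")
        assert str(sub.cigar) == "10="
        assert_matches_brute(sub, brute_subalignment(rec, 10, 20, "target"))

    def test_window_inside_deletion_is_empty_signal(self):
        rec = make_rec("50=10D50=", 100, 0, 100, "+", 110, 0, 110)
        assert subalignment_by_target(rec, 52, 58) is None

    def test_full_span_round_trip(self, identity_record):
        sub = subalignment_by_target(
            identity_record, identity_record.tstart, identity_record.tend
        )
        assert sub == identity_record


class TestSubalignmentByQuery:
    def test_identity_window(self, identity_record):
        sub = subalignment_by_query(identity_record, 10, 20)
        assert (sub.tstart, sub.tend) == (10, 20)

    def test_window_straddles_insertion(self):
        rec = make_rec("50=10I50=", 110, 0, 110, "+", 100, 0, 100)
        sub = subalignment_by_query(rec, 45, 65)
        assert str(sub.cigar) == "5=10I5="
        assert (sub.qstart, sub.qend, sub.tstart, sub.tend) == (45, 65, 45, 55)
        assert_matches_brute(sub, brute_subalignment(rec, 45, 65, "query"))

    def test_reverse_strand_window(self):
        rec = make_rec("100=", 100, 0, 100, "-", 100, 0, 100)
        sub = subalignment_by_query(rec, 10, 20)
        assert (sub.tstart, sub.tend) == (80, 90)
        assert_matches_brute(sub, brute_subalignment(rec, 10, 20, "query"))


class TestSubalignmentProperties:
    def test_random_windows_match_per_base_oracle(self):
        rng = np.random.default_rng(42)
        for seed in range(4):
            sim = random_alignment(seed, target_len=5000)
            for rec in sim.records:
                for _ in range(4):
                    lo = int(rng.integers(rec.tstart, rec.tend))
                    hi = int(rng.integers(lo + 1, rec.tend + 1))
                    sub = subalignment_by_target(rec, lo, hi)
                    exp = brute_subalignment(rec, lo, hi, "target")
                    if exp is None:
                        assert sub is None
                    else:
                        assert_matches_brute(sub, exp)
                    qlo = int(rng.integers(rec.qstart, rec.qend))
                    qhi = int(rng.integers(qlo + 1, rec.qend + 1))
                    sub = subalignment_by_query(rec, qlo, qhi)
                    exp = brute_subalignment(rec, qlo, qhi, "query")
                    if exp is None:
                        assert sub is None
                    else:
                        assert_matches_brute(sub, exp)

    def test_sub_then_sub_composes(self):
        rec = make_rec("30=5D20=4I30=", 84, 0, 84, "+", 85, 0, 85)
        once = subalignment_by_target(rec, 10, 70)
        twice = subalignment_by_query(once, 20, 60)
        direct = subalignment_by_query(subalignment_by_target(rec, 10, 70), 20, 60)
        assert twice == direct
        assert expand_kinds(twice)[0] in "=X" and expand_kinds(twice)[-1] in "=X"

    def test_aligned_column_count_identity_on_fixture(self):
        # (#=/X columns) == qspan - ins_bases == tspan - del_bases
        for rec in random_alignment(5, target_len=5000).records:
            c = count_events(rec.cigar)
            aligned = c.matches + c.mismatches
            assert aligned == rec.query_span - c.ins_bases
            assert aligned == rec.target_span - c.del_bases


class TestFlip:
    def test_coordinate_reflection(self):
        rec = make_rec("20=", 100, 10, 30, "+", 50, 0, 20)
        flipped = flip_query_orientation(rec)
        assert (flipped.strand, flipped.qstart, flipped.qend) == ("-", 70, 90)
        assert flipped.cigar == rec.cigar

    def test_involution(self):
        rec = make_rec("10=5I10=3D7=", 120, 10, 42, "-", 60, 5, 35)
        assert flip_query_orientation(flip_query_orientation(rec)) == rec

    def test_flip_describes_same_base_pairs_after_reflection(self):
        rec = make_rec("10=2D5X", 40, 12, 27, "-", 50, 20, 37)
        flipped = flip_query_orientation(rec)
        orig = brute_columns(rec)
        refl = [
            (t, rec.qlen - 1 - q if q is not None else None, k)
            for (t, q, k) in brute_columns(flipped)
        ]
        assert orig == refl

    def test_flip_drops_cs(self):
        rec = make_rec("5=", 5, 0, 5, "+", 5, 0, 5, cs=":5")
        assert flip_query_orientation(rec).cs is None


class TestInvert:
    def test_identity_swaps_names(self, identity_record):
        inv = invert_record(identity_record)
        assert (inv.qname, inv.tname) == ("t", "q")
        assert inv.cigar == identity_record.cigar

    def test_indel_ops_swap(self):
        rec = make_rec("5=3I5=", 13, 0, 13, "+", 10, 0, 10)
        inv = invert_record(rec)
        assert str(inv.cigar) == "5=3D5="
        # oracle: the inverted record's columns are the column-swapped originals
        swapped = [(q, t, {"I": "D", "D": "I"}.get(k, k)) for (t, q, k) in brute_columns(rec)]
        assert brute_columns(inv) == swapped

    def test_reverse_strand_columns_swap(self):
        rec = make_rec("4=2D3X", 20, 5, 12, "-", 30, 10, 19, cs=":4-ca*at*gc*tg")
        inv = invert_record(rec)
        inv.validate()
        key = lambda c: (c[0] is None, c[0] or 0, c[1] is None, c[1] or 0, c[2])
        swapped = sorted(
            ((q, t, {"I": "D", "D": "I"}.get(k, k)) for (t, q, k) in brute_columns(rec)),
            key=key,
        )
        assert sorted(brute_columns(inv), key=key) == swapped

    def test_involution(self):
        for cg, qlen, tlen in [("5=3I5=", 13, 10), ("4=2D6X", 10, 12)]:
            for strand in "+-":
                rec = make_rec(cg, qlen, 0, qlen, strand, tlen, 0, tlen)
                assert invert_record(invert_record(rec)) == rec

    def test_involution_preserves_cs(self):
        rec = make_rec("2=1I2=", 5, 0, 5, "-", 4, 0, 4, cs=":2+g:2")
        twice = invert_record(invert_record(rec))
        assert twice == rec

    def test_inverted_cs_consistent_with_inverted_cigar(self):
        from pafkit import cs_to_cigar

        for rec in random_alignment(9, target_len=4000).records:
            inv = invert_record(rec)
            inv.validate()
            assert cs_to_cigar(inv.cs) == inv.cigar
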