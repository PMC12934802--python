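"""Coordinate arithmetic on CIGAR-bearing PAF records.

This module is the single source of truth for alignment projection: per-base
column expansion, sub-alignment extraction by target or query range, strand
flipping and query/target inversion.  Every edit recomputes nmatch/alnlen
from the resulting CIGAR and never leaves a record that begins or ends in an
indel — a requested boundary that falls inside an insertion or deletion is
moved inward to the nearest aligned (=/X) column.

CIGARs are stored in target-forward order for both strands; a ``-`` strand
record walks the query from high to low forward-strand coordinates.  This
matches minimap2's PAF emission and makes every target-space operation
strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, NamedTuple, Optional

from .paf_io import (
    ALIGNED_KINDS,
    AMBIG_M,
    CigarError,
    CigarOp,
    CigarString,
    CsToken,
    PafRecord,
    slice_cs,
)

GAP = None  # gap sentinel in AlignedColumn


class AlignedColumn(NamedTuple):
    """One alignment column: target position, forward-strand query position
    (either may be GAP for indels) and the op kind that produced it."""

    tpos: Optional[int]
    qpos: Optional[int]
    kind: str


@dataclass(frozen=True)
class AlignmentCounts:
    matches: int = 0
    mismatches: int = 0
    ins_events: int = 0
    del_events: int = 0
    ins_bases: int = 0
    del_bases: int = 0


def count_events(cg: CigarString) -> AlignmentCounts:
    """Tally matches, mismatches and indel events/bases from a CIGAR."""
    m = x = ie = de = ib = db = 0
    for op in cg:
        if op.kind == "=":
            m += op.length
        elif op.kind == "X":
            x += op.length
        elif op.kind == "I":
            ie += 1
            ib += op.length
        elif op.kind == "D":
            de += 1
            db += op.length
        else:
            raise CigarError(
                "ambiguous M op in CIGAR; identity statistics need =/X ops "
                "(realign with e.g. `minimap2 --eqx`)"
            )
    return AlignmentCounts(m, x, ie, de, ib, db)


def aligned_columns(rec: PafRecord) -> Iterator[AlignedColumn]:
    """Expand a record into per-base columns in target-forward order.

    For strand '+' query positions ascend from qstart; for '-' they descend
    from qend-1 toward qstart (always forward-strand coordinates).
    """
    if rec.cigar is None:
        raise CigarError("aligned_columns requires a cg tag")
    t = rec.tstart
    if rec.strand == "+":
        q, dq = rec.qstart, 1
    else:
        q, dq = rec.qend - 1, -1
    for op in rec.cigar:
        k = op.kind
        if k in ALIGNED_KINDS:
            for _ in range(op.length):
                yield AlignedColumn(t, q, k)
                t += 1
                q += dq
        elif k == "I":
            for _ in range(op.length):
                yield AlignedColumn(GAP, q, k)
                q += dq
        else:  # D
            for _ in range(op.length):
                yield AlignedColumn(t, GAP, k)
                t += 1


# ---------------------------------------------------------------------------
# Run-length (op-level) slicing machinery.  aligned_columns above is the
# per-base reference; these routines do the same work in O(#ops).


def _op_offsets(cg: CigarString):
    """Yield (op, col0, q0, t0): cumulative columns / query bases / target
    bases consumed before each op, in target-forward walk order."""
    col = q = t = 0
    for op in cg:
        yield op, col, q, t
        col += op.length
        if op.consumes_query:
            q += op.length
        if op.consumes_target:
            t += op.length


def _column_range_by_target(rec: PafRecord, lo: int, hi: int):
    """First/last aligned-column indices whose target position is in [lo, hi)."""
    col_a = col_b = None
    for op, col0, _q0, t0 in _op_offsets(rec.cigar):
        if op.kind not in ALIGNED_KINDS:
            continue
        a = rec.tstart + t0
        b = a + op.length
        s, e = max(a, lo), min(b, hi)
        if s < e:
            if col_a is None:
                col_a = col0 + (s - a)
            col_b = col0 + (e - a) - 1
    if col_a is None:
        return None
    return col_a, col_b


def _column_range_by_query(rec: PafRecord, lo: int, hi: int):
    """First/last aligned-column indices whose forward-strand query position
    is in [lo, hi).  Column indices remain target-forward."""
    col_a = col_b = None
    forward = rec.strand == "+"
    for op, col0, q0, _t0 in _op_offsets(rec.cigar):
        if op.kind not in ALIGNED_KINDS:
            continue
        if forward:
            a = rec.qstart + q0
            b = a + op.length
        else:
            b = rec.qend - q0
            a = b - op.length
        s, e = max(a, lo), min(b, hi)
        if s < e:
            if forward:
                c_first = col0 + (s - a)
                c_last = col0 + (e - a) - 1
            else:
                # within the op, column index rises as qpos falls
                c_first = col0 + (b - e)
                c_last = col0 + (b - 1 - s)
            if col_a is None:
                col_a = c_first
            col_b = c_last
    if col_a is None:
        return None
    return col_a, col_b


def slice_columns(rec: PafRecord, col_a: int, col_b: int) -> PafRecord:
    """Extract alignment columns [col_a, col_b] (inclusive) as a new record.

    Both boundary columns must be aligned (=/X/M) so the result never dangles
    in an indel.  The cs tag, when present, is sliced in lock-step.
    """
    if rec.cigar is None:
        raise CigarError("slice_columns requires a cg tag")
    if col_a > col_b:
        raise CigarError("empty column slice")
    new_ops: list[CigarOp] = []
    q_before = 0
    t_before = 0
    nmatch = 0
    q_in = t_in = 0
    for op, col0, _q0, _t0 in _op_offsets(rec.cigar):
        lo = max(col0, col_a)
        hi = min(col0 + op.length, col_b + 1)
        if op.consumes_query:
            q_before += max(0, min(col0 + op.length, col_a) - col0)
        if op.consumes_target:
            t_before += max(0, min(col0 + op.length, col_a) - col0)
        if lo < hi:
            n = hi - lo
            new_ops.append(CigarOp(op.kind, n))
            if op.consumes_query:
                q_in += n
            if op.consumes_target:
                t_in += n
            if op.kind == "=":
                nmatch += n
    if not new_ops or new_ops[0].kind not in ALIGNED_KINDS or new_ops[-1].kind not in ALIGNED_KINDS:
        raise CigarError("column slice boundaries must be aligned columns")
    tstart = rec.tstart + t_before
    tend = tstart + t_in
    if rec.strand == "+":
        qstart = rec.qstart + q_before
        qend = qstart + q_in
    else:
        qend = rec.qend - q_before
        qstart = qend - q_in
    new_cs: tuple[CsToken, ...] | None = None
    dropped_cs = False
    if rec.cs is not None:
        try:
            new_cs = slice_cs(rec.cs, col_a, col_b + 1)
        except (CigarError, IndexError):
            dropped_cs = True
    out = replace(
        rec,
        qstart=qstart,
        qend=qend,
        tstart=tstart,
        tend=tend,
        nmatch=nmatch,
        alnlen=col_b + 1 - col_a,
        cigar=CigarString(new_ops),
        cs=new_cs,
        tags=dict(rec.tags),
    )
    if dropped_cs:
        out = out.drop_cs("cs tag inconsistent with CIGAR during trimming")
    return out


def subalignment_by_target(
    rec: PafRecord, lo: int, hi: int
) -> Optional[PafRecord]:
    """Trim a record to the target window [lo, hi).

    The window is further shrunk so the sub-alignment begins and ends on an
    aligned column.  Returns None when the window contains no aligned column
    (the empty-result signal, e.g. a window entirely inside a deletion).
    """
    if rec.cigar is None:
        raise CigarError("subalignment_by_target requires a cg tag")
    lo = max(lo, rec.tstart)
    hi = min(hi, rec.tend)
    if lo >= hi:
        return None
    rng = _column_range_by_target(rec, lo, hi)
    if rng is None:
        return None
    return slice_columns(rec, *rng)


def subalignment_by_query(
    rec: PafRecord, lo: int, hi: int
) -> Optional[PafRecord]:
    """Trim a record to the forward-strand query window [lo, hi)."""
    if rec.cigar is None:
        raise CigarError("subalignment_by_query requires a cg tag")
    lo = max(lo, rec.qstart)
    hi = min(hi, rec.qend)
    if lo >= hi:
        return None
    rng = _column_range_by_query(rec, lo, hi)
    if rng is None:
        return None
    return slice_columns(rec, *rng)


def flip_query_orientation(rec: PafRecord) -> PafRecord:
    """Toggle the record's strand, reflecting query coordinates through qlen.

    The CIGAR is unchanged (it stays target-forward); the cs tag is dropped.
    Applying the flip twice returns the original record (modulo a dropped cs).
    """
    out = replace(
        rec,
        strand="-" if rec.strand == "+" else "+",
        qstart=rec.qlen - rec.qend,
        qend=rec.qlen - rec.qstart,
        tags=dict(rec.tags),
    )
    return out.drop_cs("query orientation flipped")


_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _invert_cs(tokens: tuple[CsToken, ...], strand: str) -> tuple[CsToken, ...]:
    """Swap the roles of the two sequences in a cs stream.

    Insertions become deletions and vice versa; substitution bases swap.  For
    a '-' strand record the new target-forward orientation is the reverse
    complement of the old one, so token order reverses and payloads are
    reverse-complemented.
    """
    out: list[CsToken] = []
    if strand == "+":
        for tok in tokens:
            if tok.kind == ":":
                out.append(tok)
            elif tok.kind == "*":
                a, b = tok.payload  # type: ignore[misc]
                out.append(CsToken("*", b + a))
            elif tok.kind == "+":
                out.append(CsToken("-", tok.payload))
            else:
                out.append(CsToken("+", tok.payload))
        return tuple(out)
    for tok in reversed(tokens):
        if tok.kind == ":":
            out.append(tok)
        elif tok.kind == "*":
            a, b = tok.payload  # type: ignore[misc]
            out.append(CsToken("*", _revcomp(b) + _revcomp(a)))
        elif tok.kind == "+":
            out.append(CsToken("-", _revcomp(tok.payload)))  # type: ignore[arg-type]
        else:
            out.append(CsToken("+", _revcomp(tok.payload)))  # type: ignore[arg-type]
    return tuple(out)


def invert_record(rec: PafRecord) -> PafRecord:
    """Swap query and target: the alignment itself is unchanged, only which
    side is called "query".  I and D ops exchange; for a '-' strand record
    the op order reverses so the CIGAR remains new-target-forward.  An
    involution."""
    swap = {"I": "D", "D": "I"}
    ops = [CigarOp(swap.get(op.kind, op.kind), op.length) for op in (rec.cigar or ())]
    if rec.strand == "-":
        ops.reverse()
    return replace(
        rec,
        qname=rec.tname,
        qlen=rec.tlen,
        qstart=rec.tstart,
        qend=rec.tend,
        tname=rec.qname,
        tlen=rec.qlen,
        tstart=rec.qstart,
        tend=rec.qend,
        cigar=CigarString(ops) if rec.cigar is not None else None,
        cs=_invert_cs(rec.cs, rec.strand) if rec.cs is not None else None,
        tags=dict(rec.tags),
    )
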