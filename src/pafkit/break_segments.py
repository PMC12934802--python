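"""Split alignment records at large insertions or deletions.

Structural variants show up in assembly-to-assembly alignments as very long
I/D ops; cutting the alignment there turns one sprawling record into
fine-grained segments whose boundaries land on aligned bases, which is what
downstream visualization wants.
"""

from __future__ import annotations

from dataclasses import replace

from .cigar_engine import slice_columns
from .paf_io import ALIGNED_KINDS, CigarError, PafRecord


def break_on_indels(
    rec: PafRecord, max_indel: float, record_id: int = 0
) -> list[PafRecord]:
    """Cut a record at every I or D op strictly longer than ``max_indel``.

    Each maximal run of ops between cuts becomes its own record with
    recomputed coordinates; sub-threshold indels left dangling at a segment
    edge are trimmed too, so every segment begins and ends on an aligned
    column.  The oversized indel ops themselves appear in no output record.
    Segments are emitted in target order and tagged ``id:Z:{record_id}.{k}``;
    a record with no oversized indel is returned unchanged (and untagged).
    """
    if rec.cigar is None:
        raise CigarError("break_on_indels requires a cg tag")
    if max_indel < 1:
        raise ValueError("max_indel must be >= 1")
    ops = rec.cigar.ops
    cuts = [
        i for i, op in enumerate(ops) if op.kind in "ID" and op.length > max_indel
    ]
    if not cuts:
        return [rec]
    # column offset of each op
    col0 = []
    c = 0
    for op in ops:
        col0.append(c)
        c += op.length
    segments: list[PafRecord] = []
    k = 0
    prev = 0
    for cut in cuts + [len(ops)]:
        lo_op, hi_op = prev, cut
        prev = cut + 1
        # shrink to the first/last aligned column inside this op range
        col_a = col_b = None
        for i in range(lo_op, hi_op):
            if ops[i].kind in ALIGNED_KINDS:
                if col_a is None:
                    col_a = col0[i]
                col_b = col0[i] + ops[i].length - 1
        if col_a is None:
            continue
        seg = slice_columns(rec, col_a, col_b)
        tags = dict(seg.tags)
        tags["id"] = ("Z", f"{record_id}.{k}")
        seg = replace(seg, tags=tags)
        segments.append(seg)
        k += 1
    return segments
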