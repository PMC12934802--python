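"""Reorient query contigs and optionally merge them into pseudo-scaffolds.

``orient`` flips every record of a query contig when the majority of its
aligned bases map in reverse, so downstream plots read left to right.
``scaffold`` then concatenates the (oriented) contigs of each target into a
single pseudo-scaffold coordinate system, ordered by target position with a
fixed unaligned gap between consecutive contigs.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable

from .cigar_engine import flip_query_orientation
from .paf_io import PafRecord

DEFAULT_SCAFFOLD_GAP = 1000


def _aligned_query_bases(rec: PafRecord) -> int:
    # query-consuming aligned bases (=, X, I) equal the query span
    return rec.qend - rec.qstart


def orient(records: Iterable[PafRecord]) -> list[PafRecord]:
    """Flip each query contig whose reverse-aligned bases outnumber its
    forward-aligned bases.  Exact ties keep the original orientation; record
    order is preserved and the operation is idempotent."""
    recs = list(records)
    fwd: dict[str, int] = {}
    rev: dict[str, int] = {}
    for rec in recs:
        d = fwd if rec.strand == "+" else rev
        d[rec.qname] = d.get(rec.qname, 0) + _aligned_query_bases(rec)
    flip = {
        q for q in set(fwd) | set(rev) if rev.get(q, 0) > fwd.get(q, 0)
    }
    return [
        flip_query_orientation(rec) if rec.qname in flip else rec for rec in recs
    ]


def scaffold(
    records: Iterable[PafRecord], gap: int = DEFAULT_SCAFFOLD_GAP
) -> list[PafRecord]:
    """Merge query contigs into one pseudo-scaffold per target.

    Records are oriented first.  Each query contig is assigned wholly to the
    target carrying most of its aligned bases (ties to the lexicographically
    smallest target name); within a scaffold, contigs are ordered by their
    minimum tstart on that target (ties by query name).  Coordinates shift
    by the contig's offset, qname becomes ``{tname}_scaffold``, the original
    name is kept in a ``qn:Z:`` tag, and CIGARs are untouched, so per-record
    identity statistics are preserved exactly.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    recs = orient(records)
    # aligned bases per (query, target)
    weight: dict[str, dict[str, int]] = {}
    qlen: dict[str, int] = {}
    min_tstart: dict[tuple[str, str], int] = {}
    for rec in recs:
        weight.setdefault(rec.qname, {})
        weight[rec.qname][rec.tname] = (
            weight[rec.qname].get(rec.tname, 0) + _aligned_query_bases(rec)
        )
        qlen[rec.qname] = rec.qlen
        key = (rec.qname, rec.tname)
        min_tstart[key] = min(min_tstart.get(key, rec.tstart), rec.tstart)
    assigned = {
        q: min(w, key=lambda t: (-w[t], t)) for q, w in weight.items()
    }
    # per-target contig order and offsets
    offset: dict[str, int] = {}
    scaffold_len: dict[str, int] = {}
    by_target: dict[str, list[str]] = {}
    for q, t in assigned.items():
        by_target.setdefault(t, []).append(q)
    for t, queries in by_target.items():
        queries.sort(key=lambda q: (min_tstart[(q, t)], q))
        off = 0
        for i, q in enumerate(queries):
            if i:
                off += gap
            offset[q] = off
            off += qlen[q]
        scaffold_len[t] = off
    out = []
    for rec in recs:
        t = assigned[rec.qname]
        off = offset[rec.qname]
        tags = dict(rec.tags)
        tags["qn"] = ("Z", rec.qname)
        out.append(
            replace(
                rec,
                qname=f"{t}_scaffold",
                qlen=scaffold_len[t],
                qstart=rec.qstart + off,
                qend=rec.qend + off,
                tags=tags,
            )
        )
    return out
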