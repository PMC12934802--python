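"""Resolve overlapping query alignments by cumulative-score maximization.

At duplications and inversion boundaries, aligners emit supplemental records
that map the same query bases to several target positions.  ``trim_paf``
repeatedly takes the largest query-coordinate overlap, finds the split point
that maximizes the summed per-base alignment score of the left record before
the split plus the right record after it, trims both records there, and
iterates until no query base is aligned more than once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cigar_engine import subalignment_by_query
from .paf_io import CigarError, PafRecord


@dataclass(frozen=True)
class ScoreScheme:
    """Per-base alignment scores used to place the split point."""

    match: float = 1.0
    mismatch: float = -1.0
    indel_base: float = -1.0

    def __post_init__(self) -> None:
        if not self.match > 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.indel_base > 0:
            raise ValueError("mismatch and indel scores must be <= 0")


@dataclass
class OverlapPair:
    """Two records of one query whose spans intersect in [olo, ohi).

    left is the record with the smaller qstart (smaller qend on ties);
    indices refer to the record list the pair was computed from.
    """

    left: PafRecord
    right: PafRecord
    olo: int
    ohi: int
    left_index: int
    right_index: int

    @property
    def length(self) -> int:
        return self.ohi - self.olo


def find_query_overlaps(records: Sequence[PafRecord]) -> list[OverlapPair]:
    """All pairs of records sharing a query name with intersecting spans,
    sorted by overlap length descending (ties keep input pair order)."""
    by_query: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_query.setdefault(rec.qname, []).append(i)
    pairs: list[OverlapPair] = []
    for idxs in by_query.values():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                i, j = idxs[a], idxs[b]
                ra, rb = records[i], records[j]
                olo = max(ra.qstart, rb.qstart)
                ohi = min(ra.qend, rb.qend)
                if olo >= ohi:
                    continue
                if (ra.qstart, ra.qend) <= (rb.qstart, rb.qend):
                    pairs.append(OverlapPair(ra, rb, olo, ohi, i, j))
                else:
                    pairs.append(OverlapPair(rb, ra, olo, ohi, j, i))
    pairs.sort(key=lambda p: -p.length)  # stable: ties keep enumeration order
    return pairs


def _score_profile(
    rec: PafRecord, olo: int, ohi: int, scheme: ScoreScheme
) -> np.ndarray:
    """Per-query-position score of a record over the window [olo, ohi).

    Matches/mismatches/insertion bases score at their own query position.
    Deletion bases consume no query, so their penalty attaches to the query
    position of the next aligned column in the target-forward walk — a split
    therefore never lands inside a deletion.
    """
    if rec.cigar is None:
        raise CigarError("overlap trimming requires cg tags")
    prof = np.zeros(ohi - olo, dtype=float)

    def deposit(qa: int, qb: int, score: float) -> None:
        s, e = max(qa, olo), min(qb, ohi)
        if s < e:
            prof[s - olo : e - olo] += score

    forward = rec.strand == "+"
    qcur = rec.qstart if forward else rec.qend
    pending = 0.0
    for op in rec.cigar:
        k, n = op.kind, op.length
        if k in "=XM":
            if k == "M":
                raise CigarError(
                    "ambiguous M op; overlap scoring needs =/X ops (use --eqx)"
                )
            if forward:
                qa, qb = qcur, qcur + n
                first_q = qa
                qcur = qb
            else:
                qb, qa = qcur, qcur - n
                first_q = qb - 1
                qcur = qa
            if pending and olo <= first_q < ohi:
                prof[first_q - olo] += pending
            pending = 0.0
            deposit(qa, qb, scheme.match if k == "=" else scheme.mismatch)
        elif k == "I":
            if forward:
                qa, qb = qcur, qcur + n
                qcur = qb
            else:
                qb, qa = qcur, qcur - n
                qcur = qa
            deposit(qa, qb, scheme.indel_base)
        else:  # D consumes no query
            pending += scheme.indel_base * n
    return prof


def best_split(pair: OverlapPair, scheme: ScoreScheme | None = None) -> int:
    """The query coordinate p* in [olo, ohi] maximizing
    F_left(p*) + S_right(p*); ties break to the smallest coordinate."""
    scheme = scheme or ScoreScheme()
    s_left = _score_profile(pair.left, pair.olo, pair.ohi, scheme)
    s_right = _score_profile(pair.right, pair.olo, pair.ohi, scheme)
    n = pair.ohi - pair.olo
    prefix_left = np.concatenate(([0.0], np.cumsum(s_left)))  # F(olo+k)
    suffix_right = np.concatenate((np.cumsum(s_right[::-1])[::-1], [0.0]))
    total = prefix_left + suffix_right
    return pair.olo + int(np.argmax(total))  # argmax returns the first maximum


def split_total_score(
    pair: OverlapPair, p: int, scheme: ScoreScheme | None = None
) -> float:
    """Score of resolving ``pair`` at split point p (left keeps [olo, p),
    right keeps [p, ohi))."""
    scheme = scheme or ScoreScheme()
    s_left = _score_profile(pair.left, pair.olo, pair.ohi, scheme)
    s_right = _score_profile(pair.right, pair.olo, pair.ohi, scheme)
    k = p - pair.olo
    return float(s_left[:k].sum() + s_right[k:].sum())


def trim_paf(
    records: Iterable[PafRecord], scheme: ScoreScheme | None = None
) -> list[PafRecord]:
    """Trim records until no query base is aligned more than once.

    Iterates from the largest overlap; each resolution trims the left record
    to query end p* over the overlap and the right record to query start p*.
    When the left record extends beyond the overlap (containment), its tail
    past the overlap survives as a separate piece, so a contained record is
    resolved by two boundary splits — or dropped outright when its best
    retained span holds no aligned column.  Surviving input order is
    preserved and the result is deterministic and idempotent.
    """
    scheme = scheme or ScoreScheme()
    # sort keys are tuples so a split-off tail can slot in after its parent
    live: dict[tuple, PafRecord] = {(i,): rec for i, rec in enumerate(records)}
    n_tails = 0
    while True:
        order = sorted(live)
        pairs = find_query_overlaps([live[k] for k in order])
        if not pairs:
            break
        top = pairs[0]
        lk, rk = order[top.left_index], order[top.right_index]
        p = best_split(top, scheme)
        left, right = live[lk], live[rk]
        new_left = subalignment_by_query(left, left.qstart, p) if p > left.qstart else None
        tail = (
            subalignment_by_query(left, top.ohi, left.qend)
            if left.qend > top.ohi
            else None
        )
        new_right = subalignment_by_query(right, p, right.qend) if p < right.qend else None
        if new_left is None:
            del live[lk]
        else:
            live[lk] = new_left
        if tail is not None:
            n_tails += 1
            live[lk + (1, n_tails)] = tail
        if new_right is None:
            del live[rk]
        else:
            live[rk] = new_right
    return [live[k] for k in sorted(live)]
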