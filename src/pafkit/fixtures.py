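"""Deterministic synthetic query/target alignments with a base-level truth map.

The generator plants structural events (tandem duplications, inversions,
large insertions/deletions) and substitution regions on a toy target genome
and writes out the PAF records a well-behaved ``--eqx`` aligner would produce
for the derived query, together with a :class:`TruthMap` recording every
homologous base pair and every planted substitution.  Because CIGARs are
constructed directly from the event list (no aligner in the loop), every
downstream module has an exact oracle.

Event semantics, on the target axis:

* ``SUBST_RATE(position, length, rate)`` — each base in the region is
  substituted independently with probability ``rate``; realized positions are
  recorded.
* ``INSERTION(position, length)`` — the query gains ``length`` novel bases at
  that target position (an I op).
* ``DELETION(position, length)`` — the query lacks the target bases
  ``[position, position+length)`` (a D op).
* ``TANDEM_DUP(position, length)`` — the target carries two identical copies
  of an ``length``-bp unit at ``[position, position+2*length)`` while the
  query has one; the single query copy aligns to both target copies, which
  yields two PAF records overlapping by exactly ``length`` query bases (the
  overlap-trimming scenario).
* ``INVERSION(position, length)`` — the homologous query segment is
  reverse-complemented, yielding a ``-`` strand record flanked by ``+``
  records.

Structural events must not touch the first or last target base and must be
separated by at least one unaffected base, which guarantees every emitted
record begins and ends on an aligned column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .paf_io import CigarString, PafRecord, parse_cs

SUBST_RATE = "SUBST_RATE"
INSERTION = "INSERTION"
DELETION = "DELETION"
TANDEM_DUP = "TANDEM_DUP"
INVERSION = "INVERSION"
SV_KINDS = (SUBST_RATE, INSERTION, DELETION, TANDEM_DUP, INVERSION)

_BASES = "ACGT"
_BASES_LOWER = "acgt"
TARGET_NAME = "tgt"
QUERY_NAME = "qry"


@dataclass(frozen=True)
class SvSpec:
    """One planted event; see the module docstring for semantics."""

    kind: str
    position: int
    length: int = 0
    rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SV_KINDS:
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.length < 1:
            raise ValueError(f"{self.kind} length must be >= 1")
        if self.kind == SUBST_RATE and not 0.0 <= self.rate <= 1.0:
            raise ValueError("substitution rate must be in [0, 1]")

    @property
    def target_span(self) -> int:
        """Bases of target occupied by the event."""
        if self.kind == TANDEM_DUP:
            return 2 * self.length
        if self.kind == INSERTION:
            return 0
        return self.length


def _validate_svs(target_len: int, svs: Sequence[SvSpec]) -> list[SvSpec]:
    svs = sorted(svs, key=lambda s: s.position)
    prev_end = 0  # events must start at >=1, so first gap check uses end 0
    for sv in svs:
        if sv.position < 1:
            raise ValueError(f"{sv.kind} at {sv.position}: events must start at >= 1")
        if sv.position < prev_end + 1:
            raise ValueError(
                f"{sv.kind} at {sv.position} overlaps or touches the previous event"
            )
        end = sv.position + sv.target_span
        if end > target_len - 1:
            raise ValueError(
                f"{sv.kind} at {sv.position} (span {sv.target_span}) reaches the "
                f"last base of a {target_len}-bp target"
            )
        prev_end = end
    return svs


class TruthMap:
    """Ground-truth base-level correspondence between query and target.

    Stores one (target, query, orientation) triple per homologous base pair
    plus the planted substitution positions (target coordinates).
    """

    def __init__(
        self, tpos: np.ndarray, qpos: np.ndarray, reverse: np.ndarray, edits: np.ndarray
    ):
        self.tpos = np.asarray(tpos, dtype=np.int64)
        self.qpos = np.asarray(qpos, dtype=np.int64)
        self.reverse = np.asarray(reverse, dtype=bool)
        self.edits = np.asarray(edits, dtype=np.int64)
        self._pairs: frozenset | None = None

    def __len__(self) -> int:
        return len(self.tpos)

    def pairs(self) -> frozenset:
        """The correspondence as a set of (tpos, qpos, '+'|'-') triples."""
        if self._pairs is None:
            self._pairs = frozenset(
                zip(
                    self.tpos.tolist(),
                    self.qpos.tolist(),
                    np.where(self.reverse, "-", "+").tolist(),
                )
            )
        return self._pairs

    def query_image(self, lo: int, hi: int) -> np.ndarray:
        """Sorted unique query positions homologous to target [lo, hi)."""
        mask = (self.tpos >= lo) & (self.tpos < hi)
        return np.unique(self.qpos[mask])


@dataclass
class Simulation:
    """Output bundle of :func:`simulate_alignment`."""

    truth: TruthMap
    records: list[PafRecord]
    svs: list[SvSpec]
    target_len: int
    query_len: int
    target_codes: np.ndarray = field(repr=False)
    query_codes: np.ndarray = field(repr=False)

    def target_fasta(self) -> str:
        return f">{TARGET_NAME}\n{_decode(self.target_codes)}\n"

    def query_fasta(self) -> str:
        return f">{QUERY_NAME}\n{_decode(self.query_codes)}\n"


def _decode(codes: np.ndarray) -> str:
    return bytes(np.frombuffer(_BASES.encode(), dtype=np.uint8)[codes]).decode()


def _lower(codes: np.ndarray) -> str:
    return bytes(np.frombuffer(_BASES_LOWER.encode(), dtype=np.uint8)[codes]).decode()


class _RecordDraft:
    """A PAF record under construction during the target walk."""

    def __init__(self, t0: int, q0: int, strand: str = "+"):
        self.t0 = t0
        self.q0 = q0
        self.strand = strand
        self.ops: list[list] = []  # [kind, length], adjacent same-kind merged
        self.cs: list[str] = []

    def add(self, kind: str, length: int, cs_part: str) -> None:
        if self.ops and self.ops[-1][0] == kind:
            self.ops[-1][1] += length
        else:
            self.ops.append([kind, length])
        self.cs.append(cs_part)


def simulate_alignment(
    target_len: int,
    svs: Iterable[SvSpec],
    seed,
    with_cs: bool = True,
) -> Simulation:
    """Generate the alignment a faithful aligner would report for a query
    derived from a random ``target_len``-bp target by the planted events.

    ``seed`` may be an integer or a ``numpy.random.Generator``; output is
    deterministic for a fixed seed and event list.
    """
    rng = np.random.default_rng(seed)
    svs = _validate_svs(target_len, list(svs))

    tseq = rng.integers(0, 4, target_len, dtype=np.int8)
    for sv in svs:
        if sv.kind == TANDEM_DUP:  # the two target copies are identical
            p, L = sv.position, sv.length
            tseq[p + L : p + 2 * L] = tseq[p : p + L]

    # realized substitutions: positions and replacement bases
    sub_pos_parts = []
    for sv in svs:
        if sv.kind == SUBST_RATE:
            hit = np.nonzero(rng.random(sv.length) < sv.rate)[0]
            sub_pos_parts.append(sv.position + hit)
    sub_pos = (
        np.concatenate(sub_pos_parts) if sub_pos_parts else np.empty(0, dtype=np.int64)
    )
    sub_new = (tseq[sub_pos] + rng.integers(1, 4, len(sub_pos))) % 4

    qparts: list[np.ndarray] = []
    truth_t: list[np.ndarray] = []
    truth_q: list[np.ndarray] = []
    truth_rev: list[np.ndarray] = []
    drafts: list[_RecordDraft] = []

    state = {"t": 0, "q": 0, "frontier": 0}
    current = _RecordDraft(0, 0)

    def emit_query(arr: np.ndarray) -> None:
        assert state["q"] == state["frontier"]
        qparts.append(arr)
        state["frontier"] += len(arr)

    def add_truth(t_arr: np.ndarray, q_arr: np.ndarray, rev: bool) -> None:
        truth_t.append(t_arr)
        truth_q.append(q_arr)
        truth_rev.append(np.full(len(t_arr), rev))

    def fill(a: int, b: int) -> None:
        """Inline aligned region over target [a, b) with planted subs."""
        if a >= b:
            return
        i0, i1 = np.searchsorted(sub_pos, [a, b])
        qarr = tseq[a:b].copy()
        prev = a
        for k in range(i0, i1):
            s = int(sub_pos[k])
            if s > prev:
                current.add("=", s - prev, f":{s - prev}")
            newb = int(sub_new[k])
            qarr[s - a] = newb
            current.add("X", 1, f"*{_BASES_LOWER[tseq[s]]}{_BASES_LOWER[newb]}")
            prev = s + 1
        if b > prev:
            current.add("=", b - prev, f":{b - prev}")
        emit_query(qarr)
        add_truth(
            np.arange(a, b), np.arange(state["q"], state["q"] + (b - a)), False
        )
        state["q"] += b - a
        state["t"] = b

    def close() -> None:
        nonlocal current
        if current.ops:
            draft = current
            draft.t1 = state["t"]  # type: ignore[attr-defined]
            draft.q1 = state["q"]  # type: ignore[attr-defined]
            drafts.append(draft)

    for sv in svs:
        p, L = sv.position, sv.length
        if sv.kind == SUBST_RATE:
            continue  # realized inside fill()
        fill(state["t"], p)
        if sv.kind == INSERTION:
            ins = rng.integers(0, 4, L, dtype=np.int8)
            current.add("I", L, f"+{_lower(ins)}")
            emit_query(ins)
            state["q"] += L
        elif sv.kind == DELETION:
            current.add("D", L, f"-{_lower(tseq[p : p + L])}")
            state["t"] = p + L
        elif sv.kind == INVERSION:
            close()
            qp = state["q"]
            inv = _RecordDraft(p, qp, strand="-")
            inv.add("=", L, f":{L}")
            inv.t1 = p + L  # type: ignore[attr-defined]
            inv.q1 = qp + L  # type: ignore[attr-defined]
            drafts.append(inv)
            emit_query((3 - tseq[p : p + L])[::-1].copy())
            add_truth(np.arange(p, p + L), np.arange(qp + L - 1, qp - 1, -1), True)
            state["q"] = qp + L
            state["t"] = p + L
            current = _RecordDraft(state["t"], state["q"])
        elif sv.kind == TANDEM_DUP:
            qp = state["q"]
            # first target copy rides in the current record
            current.add("=", L, f":{L}")
            emit_query(tseq[p : p + L].copy())
            add_truth(np.arange(p, p + L), np.arange(qp, qp + L), False)
            state["q"] = qp + L
            state["t"] = p + L
            close()
            # second target copy re-aligns the same query bases
            current = _RecordDraft(p + L, qp)
            current.add("=", L, f":{L}")
            add_truth(np.arange(p + L, p + 2 * L), np.arange(qp, qp + L), False)
            state["t"] = p + 2 * L
    fill(state["t"], target_len)
    close()

    qlen = state["q"]
    qseq = np.concatenate(qparts) if qparts else np.empty(0, dtype=np.int8)
    assert len(qseq) == qlen

    records = []
    for d in drafts:
        cg = CigarString([(k, n) for k, n in d.ops])
        rec = PafRecord(
            qname=QUERY_NAME,
            qlen=qlen,
            qstart=d.q0,
            qend=d.q1,
            strand=d.strand,
            tname=TARGET_NAME,
            tlen=target_len,
            tstart=d.t0,
            tend=d.t1,
            nmatch=sum(n for k, n in d.ops if k == "="),
            alnlen=sum(n for _k, n in d.ops),
            mapq=60,
            cigar=cg,
            cs=parse_cs("".join(d.cs)) if with_cs else None,
            tag_order=("cg", "cs") if with_cs else ("cg",),
        )
        rec.validate()
        records.append(rec)

    truth = TruthMap(
        np.concatenate(truth_t) if truth_t else np.empty(0, dtype=np.int64),
        np.concatenate(truth_q) if truth_q else np.empty(0, dtype=np.int64),
        np.concatenate(truth_rev) if truth_rev else np.empty(0, dtype=bool),
        np.sort(sub_pos),
    )
    return Simulation(
        truth=truth,
        records=records,
        svs=svs,
        target_len=target_len,
        query_len=qlen,
        target_codes=tseq,
        query_codes=qseq,
    )


def random_svspecs(
    rng,
    target_len: int,
    n_events: int = 6,
    max_indel: int = 2000,
    weights: dict[str, float] | None = None,
    dup_len: tuple[int, int] = (100, 500),
    inv_len: tuple[int, int] = (100, 500),
    sub_len: tuple[int, int] = (200, 2000),
    sub_rate: tuple[float, float] = (0.005, 0.05),
) -> list[SvSpec]:
    """Draw a random non-overlapping event list for :func:`simulate_alignment`.

    Indel lengths are log-uniform on [1, max_indel] so both single-base and
    near-threshold events occur.  Placement walks left to right with random
    gaps; fewer than ``n_events`` may fit on a short target.
    """
    rng = np.random.default_rng(rng)
    weights = weights or {
        SUBST_RATE: 0.3,
        INSERTION: 0.2,
        DELETION: 0.2,
        TANDEM_DUP: 0.15,
        INVERSION: 0.15,
    }
    kinds = list(weights)
    probs = np.array([weights[k] for k in kinds], dtype=float)
    probs /= probs.sum()
    max_gap = max(2, target_len // (n_events + 1))
    pos = 1 + int(rng.integers(0, max_gap))
    svs: list[SvSpec] = []
    while len(svs) < n_events:
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        if kind in (INSERTION, DELETION):
            length = int(round(math.exp(rng.uniform(0.0, math.log(max_indel)))))
            length = min(max(length, 1), max_indel)
            rate = 0.0
        elif kind == TANDEM_DUP:
            length = int(rng.integers(dup_len[0], dup_len[1] + 1))
            rate = 0.0
        elif kind == INVERSION:
            length = int(rng.integers(inv_len[0], inv_len[1] + 1))
            rate = 0.0
        else:
            length = int(rng.integers(sub_len[0], sub_len[1] + 1))
            rate = float(rng.uniform(sub_rate[0], sub_rate[1]))
        sv = SvSpec(kind, pos, length, rate)
        if pos + sv.target_span > target_len - 1:
            break
        svs.append(sv)
        pos = pos + sv.target_span + 1 + int(rng.integers(1, max_gap))
    return svs


def random_alignment(seed, target_len: int = 30000, **kwargs) -> Simulation:
    """One random scenario: draw events, then simulate, from a single seed."""
    rng = np.random.default_rng(seed)
    svs = random_svspecs(rng, target_len, **kwargs)
    return simulate_alignment(target_len, svs, rng)
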