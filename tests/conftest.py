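"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately work per base with plain Python lists and
dicts — no run-length arithmetic — so they stay independent of the op-level
implementations they check.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from pafkit import PafRecord, parse_paf_line

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_rec(
    cg: str,
    qlen: int,
    qstart: int,
    qend: int,
    strand: str,
    tlen: int,
    tstart: int,
    tend: int,
    qname: str = "q",
    tname: str = "t",
    mapq: int = 60,
    cs: str | None = None,
) -> PafRecord:
    """Build a validated record from a CIGAR text via the PAF parser."""
    nmatch = alnlen = 0
    num = ""
    for ch in cg:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            alnlen += n
            if ch == "=":
                nmatch += n
    line = "\t".join(
        [
            qname,
            str(qlen),
            str(qstart),
            str(qend),
            strand,
            tname,
            str(tlen),
            str(tstart),
            str(tend),
            str(nmatch),
            str(alnlen),
            str(mapq),
            f"cg:Z:{cg}",
        ]
        + ([f"cs:Z:{cs}"] if cs else [])
    )
    return parse_paf_line(line)


def brute_columns(rec: PafRecord) -> list[tuple]:
    """Per-base expansion of a record: (tpos|None, qpos|None, kind) in
    target-forward order, query positions on the forward strand."""
    cols = []
    t = rec.tstart
    q = rec.qstart if rec.strand == "+" else rec.qend - 1
    step = 1 if rec.strand == "+" else -1
    for op in rec.cigar:
        for _ in range(op.length):
            if op.kind in "=XM":
                cols.append((t, q, op.kind))
                t += 1
                q += step
            elif op.kind == "I":
                cols.append((None, q, "I"))
                q += step
            else:
                cols.append((t, None, "D"))
                t += 1
    return cols


def brute_subalignment(rec: PafRecord, lo: int, hi: int, space: str):
    """Expected sub-alignment for a window, from the per-base expansion.

    Returns None when no aligned column falls in the window, else a dict of
    the expected coordinates and the per-base kind string.
    """
    key = 0 if space == "target" else 1
    cols = brute_columns(rec)
    idx = [
        i
        for i, c in enumerate(cols)
        if c[2] in "=X" and c[key] is not None and lo <= c[key] < hi
    ]
    if not idx:
        return None
    sel = cols[min(idx) : max(idx) + 1]
    tp = [c[0] for c in sel if c[0] is not None]
    qp = [c[1] for c in sel if c[1] is not None]
    return {
        "tstart": min(tp),
        "tend": max(tp) + 1,
        "qstart": min(qp),
        "qend": max(qp) + 1,
        "kinds": "".join(c[2] for c in sel),
    }


def expand_kinds(rec: PafRecord) -> str:
    """A record's CIGAR as a per-base kind string."""
    return "".join(op.kind * op.length for op in rec.cigar)


def assert_matches_brute(sub, expected) -> None:
    assert sub is not None and expected is not None
    assert (sub.tstart, sub.tend, sub.qstart, sub.qend) == (
        expected["tstart"],
        expected["tend"],
        expected["qstart"],
        expected["qend"],
    )
    assert expand_kinds(sub) == expected["kinds"]
    sub.validate()


def brute_score_buckets(rec: PafRecord, scheme) -> dict[int, float]:
    """Per-query-position score of a record; deletion penalties attach to
    the query position of the next aligned column in target-forward order."""
    buckets: dict[int, float] = {}
    pending = 0.0
    for t, q, k in brute_columns(rec):
        if k in "=X":
            sc = scheme.match if k == "=" else scheme.mismatch
            buckets[q] = buckets.get(q, 0.0) + sc + pending
            pending = 0.0
        elif k == "I":
            buckets[q] = buckets.get(q, 0.0) + scheme.indel_base
        else:
            pending += scheme.indel_base
    return buckets


def brute_best_split(left, right, olo, ohi, scheme):
    """Exhaustive enumeration of all split points; returns (p*, best score)
    with ties going to the smallest split coordinate."""
    bl = brute_score_buckets(left, scheme)
    br = brute_score_buckets(right, scheme)
    best = None
    for p in range(olo, ohi + 1):
        tot = sum(v for q, v in bl.items() if olo <= q < p) + sum(
            v for q, v in br.items() if p <= q < ohi
        )
        if best is None or tot > best[1] + 1e-9:
            best = (p, tot)
    return best


@pytest.fixture
def identity_record() -> PafRecord:
    return make_rec("100=", 100, 0, 100, "+", 100, 0, 100)
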