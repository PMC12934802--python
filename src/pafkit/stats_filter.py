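"""Per-alignment identity statistics and record-level filters.

Three percent-identity flavors differ only in denominator:

* ``perID_by_matches``  = 100·m / (m + x)
* ``perID_by_events``   = 100·m / (m + x + ins_events + del_events)
* ``perID_by_all``      = 100·m / (m + x + ins_bases + del_bases)

with m = matched bases and x = mismatched bases taken straight from the
CIGAR.  The denominators nest, so the three values are non-increasing in
that order.  Rows serialize to a BED-style table (the dialect the ribbon
plotter consumes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .cigar_engine import AlignmentCounts, count_events
from .paf_io import PafParseError, PafRecord

logger = logging.getLogger("pafkit")

STATS_COLUMNS = (
    "tname",
    "tstart",
    "tend",
    "qname",
    "qstart",
    "qend",
    "strand",
    "perID_by_matches",
    "perID_by_events",
    "perID_by_all",
    "matches",
    "mismatches",
    "ins_events",
    "del_events",
    "ins_bases",
    "del_bases",
)
STATS_HEADER = "#" + "\t".join(STATS_COLUMNS)


@dataclass(frozen=True)
class StatsRow:
    tname: str
    tstart: int
    tend: int
    qname: str
    qstart: int
    qend: int
    strand: str
    perID_by_matches: float
    perID_by_events: float
    perID_by_all: float
    counts: AlignmentCounts


def alignment_stats(rec: PafRecord) -> StatsRow:
    """Compute one identity/coverage row from a record's CIGAR (or cs tag).

    A record with no aligned column emits zeros with a warning rather than
    aborting a stream.
    """
    counts = count_events(rec.effective_cigar())
    m, x = counts.matches, counts.mismatches
    if m + x == 0:
        logger.warning(
            "record %s->%s has no aligned columns; identities reported as 0",
            rec.qname,
            rec.tname,
        )
        by_matches = by_events = by_all = 0.0
    else:
        by_matches = 100.0 * m / (m + x)
        by_events = 100.0 * m / (m + x + counts.ins_events + counts.del_events)
        by_all = 100.0 * m / (m + x + counts.ins_bases + counts.del_bases)
    return StatsRow(
        tname=rec.tname,
        tstart=rec.tstart,
        tend=rec.tend,
        qname=rec.qname,
        qstart=rec.qstart,
        qend=rec.qend,
        strand=rec.strand,
        perID_by_matches=by_matches,
        perID_by_events=by_events,
        perID_by_all=by_all,
        counts=counts,
    )


def format_stats_row(row: StatsRow) -> str:
    c = row.counts
    return "\t".join(
        [
            row.tname,
            str(row.tstart),
            str(row.tend),
            row.qname,
            str(row.qstart),
            str(row.qend),
            row.strand,
            f"{row.perID_by_matches:.4f}",
            f"{row.perID_by_events:.4f}",
            f"{row.perID_by_all:.4f}",
            str(c.matches),
            str(c.mismatches),
            str(c.ins_events),
            str(c.del_events),
            str(c.ins_bases),
            str(c.del_bases),
        ]
    )


def parse_stats_line(line: str, line_number: int | None = None) -> StatsRow:
    where = f" at line {line_number}" if line_number is not None else ""
    cols = line.rstrip("\n").split("\t")
    if len(cols) < len(STATS_COLUMNS):
        raise PafParseError(
            f"expected {len(STATS_COLUMNS)} stats columns, got {len(cols)}{where}"
        )
    try:
        return StatsRow(
            tname=cols[0],
            tstart=int(cols[1]),
            tend=int(cols[2]),
            qname=cols[3],
            qstart=int(cols[4]),
            qend=int(cols[5]),
            strand=cols[6],
            perID_by_matches=float(cols[7]),
            perID_by_events=float(cols[8]),
            perID_by_all=float(cols[9]),
            counts=AlignmentCounts(*(int(v) for v in cols[10:16])),
        )
    except ValueError as exc:
        raise PafParseError(f"malformed stats row{where}: {exc}") from None


def read_stats(source) -> list[StatsRow]:
    from .paf_io import _open_text

    stream, close = _open_text(source)
    try:
        rows = []
        for i, line in enumerate(stream, 1):
            if not line.strip() or line.startswith("#"):
                continue
            rows.append(parse_stats_line(line, line_number=i))
        return rows
    finally:
        if close:
            stream.close()


def filter_paired_len(
    records: Iterable[PafRecord], min_len: int
) -> list[PafRecord]:
    """Keep a (qname, tname) pair's records iff their summed alignment block
    length reaches ``min_len``; record order is preserved."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    recs = list(records)
    totals: dict[tuple[str, str], int] = {}
    for rec in recs:
        key = (rec.qname, rec.tname)
        totals[key] = totals.get(key, 0) + rec.alnlen
    return [rec for rec in recs if totals[(rec.qname, rec.tname)] >= min_len]
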