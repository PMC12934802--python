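"""Reading and writing PAF records, CIGAR strings, cs difference strings, and BED.

All coordinates are 0-based half-open, the native convention of both PAF and
BED.  Query coordinates always live on the query's forward strand; for a
``-`` strand record the CIGAR is stored in *target-forward* order (the query
is walked from high to low forward-strand coordinates), matching how minimap2
emits PAF.

The parsed :class:`PafRecord` is the in-memory currency of the whole package:
every downstream operation consumes and produces these objects, and every
edit keeps the CIGAR (and, where possible, the cs string) consistent with the
record's coordinate spans.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

logger = logging.getLogger("pafkit")

# CIGAR op kinds (minimap2 --eqx vocabulary).  "M" is accepted on input but
# rejected by identity statistics, which need =/X resolution.
MATCH_EQ = "="
MISMATCH_X = "X"
INS_I = "I"
DEL_D = "D"
AMBIG_M = "M"

CIGAR_KINDS = frozenset("=XIDM")
QUERY_CONSUMING = frozenset("=XIM")
TARGET_CONSUMING = frozenset("=XDM")
ALIGNED_KINDS = frozenset("=XM")  # consume both query and target

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_CS_RE = re.compile(r"(:\d+|\*[A-Za-z]{2}|\+[A-Za-z]+|-[A-Za-z]+)")
_TAG_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]):([AifZHBc]):(.*)$", re.S)

Source = Union[str, Path, IO[str]]


class PafParseError(ValueError):
    """Malformed PAF/BED/CIGAR/cs input."""


class CigarError(ValueError):
    """A CIGAR operation was requested on an incompatible record."""


@dataclass(frozen=True)
class CigarOp:
    """One run-length CIGAR operation."""

    kind: str
    length: int

    def __post_init__(self) -> None:
        if self.kind not in CIGAR_KINDS:
            raise PafParseError(f"unknown CIGAR op kind {self.kind!r}")
        if self.length < 1:
            raise PafParseError(f"CIGAR op length must be >= 1, got {self.length}")

    @property
    def consumes_query(self) -> bool:
        return self.kind in QUERY_CONSUMING

    @property
    def consumes_target(self) -> bool:
        return self.kind in TARGET_CONSUMING

    def __str__(self) -> str:
        return f"{self.length}{self.kind}"


class CigarString:
    """An ordered, normalized sequence of :class:`CigarOp`.

    Normalized means no two adjacent ops share a kind; construction merges
    adjacent same-kind runs, so normalization is idempotent by definition.
    """

    __slots__ = ("ops",)

    def __init__(self, ops: Iterable[CigarOp | tuple[str, int]]):
        merged: list[CigarOp] = []
        for op in ops:
            if isinstance(op, tuple):
                op = CigarOp(*op)
            if merged and merged[-1].kind == op.kind:
                merged[-1] = CigarOp(op.kind, merged[-1].length + op.length)
            else:
                merged.append(op)
        self.ops: tuple[CigarOp, ...] = tuple(merged)

    @classmethod
    def parse(cls, text: str) -> "CigarString":
        if not text:
            return cls(())
        pos = 0
        ops = []
        for m in _CIGAR_RE.finditer(text):
            if m.start() != pos:
                raise PafParseError(f"unparseable CIGAR near {text[pos:pos+10]!r}")
            ops.append(CigarOp(m.group(2), int(m.group(1))))
            pos = m.end()
        if pos != len(text):
            raise PafParseError(f"unparseable CIGAR near {text[pos:pos+10]!r}")
        return cls(ops)

    def __iter__(self) -> Iterator[CigarOp]:
        return iter(self.ops)

    def __len__(self) -> int:
        return len(self.ops)

    def __bool__(self) -> bool:
        return bool(self.ops)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CigarString) and self.ops == other.ops

    def __hash__(self) -> int:
        return hash(self.ops)

    def __str__(self) -> str:
        return "".join(map(str, self.ops))

    def __repr__(self) -> str:
        return f"CigarString({str(self)!r})"

    @property
    def query_consumed(self) -> int:
        return sum(op.length for op in self.ops if op.consumes_query)

    @property
    def target_consumed(self) -> int:
        return sum(op.length for op in self.ops if op.consumes_target)

    @property
    def n_columns(self) -> int:
        """Total alignment columns (sum of all op lengths)."""
        return sum(op.length for op in self.ops)


# ---------------------------------------------------------------------------
# cs difference strings


@dataclass(frozen=True)
class CsToken:
    """One token of a minimap2 cs (short form) difference string.

    kind is one of ``:`` (identity run, payload = int length), ``*``
    (substitution, payload = two bases "ab" target then query), ``+``
    (insertion, payload = inserted query sequence) and ``-`` (deletion,
    payload = deleted target sequence).
    """

    kind: str
    payload: Union[int, str]

    @property
    def n_columns(self) -> int:
        if self.kind == ":":
            return int(self.payload)
        if self.kind == "*":
            return 1
        return len(self.payload)  # type: ignore[arg-type]

    def __str__(self) -> str:
        return f"{self.kind}{self.payload}"


def parse_cs(text: str) -> tuple[CsToken, ...]:
    pos = 0
    toks: list[CsToken] = []
    for m in _CS_RE.finditer(text):
        if m.start() != pos:
            raise PafParseError(f"unparseable cs token near {text[pos:pos+10]!r}")
        raw = m.group(1)
        if raw[0] == ":":
            toks.append(CsToken(":", int(raw[1:])))
        else:
            toks.append(CsToken(raw[0], raw[1:]))
        pos = m.end()
    if pos != len(text):
        raise PafParseError(f"unparseable cs token near {text[pos:pos+10]!r}")
    return tuple(toks)


def format_cs(tokens: Sequence[CsToken]) -> str:
    return "".join(map(str, tokens))


def cs_to_cigar(tokens: Sequence[CsToken]) -> CigarString:
    """Lossy projection of a cs token stream onto =/X/I/D CIGAR ops."""
    kind_map = {":": MATCH_EQ, "*": MISMATCH_X, "+": INS_I, "-": DEL_D}
    ops = []
    for tok in tokens:
        if tok.kind not in kind_map:
            raise PafParseError(f"unknown cs token kind {tok.kind!r}")
        n = tok.n_columns
        if n > 0:
            ops.append(CigarOp(kind_map[tok.kind], n))
    return CigarString(ops)


def slice_cs(tokens: Sequence[CsToken], col_lo: int, col_hi: int) -> tuple[CsToken, ...]:
    """Slice a cs stream by alignment-column index [col_lo, col_hi).

    Column indexing matches the CIGAR column space (target-forward order),
    which keeps cs edits in lock-step with CIGAR edits.
    """
    if not 0 <= col_lo < col_hi:
        raise CigarError(f"bad cs column slice [{col_lo}, {col_hi})")
    out: list[CsToken] = []
    col = 0
    for tok in tokens:
        n = tok.n_columns
        lo = max(col, col_lo)
        hi = min(col + n, col_hi)
        if lo < hi:
            if tok.kind == ":":
                out.append(CsToken(":", hi - lo))
            elif tok.kind == "*":
                out.append(tok)
            else:
                seq = tok.payload[lo - col : hi - col]  # type: ignore[index]
                out.append(CsToken(tok.kind, seq))
        col += n
    if col < col_hi:
        raise CigarError("cs string shorter than requested column range")
    return tuple(out)


# ---------------------------------------------------------------------------
# PAF records


@dataclass
class PafRecord:
    """One PAF alignment record (12 mandatory columns plus typed tags).

    ``cigar`` and ``cs`` hold the parsed cg:Z:/cs:Z: tags and are
    authoritative; ``tags`` holds every other tag as raw text keyed by name,
    and ``tag_order`` remembers the on-disk tag order for faithful output.
    """

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int
    cigar: CigarString | None = None
    cs: tuple[CsToken, ...] | None = None
    tags: dict[str, tuple[str, str]] = field(default_factory=dict)
    tag_order: tuple[str, ...] = ()

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart

    @property
    def target_span(self) -> int:
        return self.tend - self.tstart

    def effective_cigar(self) -> CigarString:
        """The cg tag, or the cs tag converted to CIGAR when cg is absent."""
        if self.cigar is not None:
            return self.cigar
        if self.cs is not None:
            return cs_to_cigar(self.cs)
        raise CigarError(
            f"record {self.qname}->{self.tname} carries neither cg nor cs tag"
        )

    def validate(self) -> None:
        if self.strand not in "+-":
            raise PafParseError(f"bad strand {self.strand!r}")
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise PafParseError(
                f"bad query coordinates {self.qstart}-{self.qend} (qlen {self.qlen})"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise PafParseError(
                f"bad target coordinates {self.tstart}-{self.tend} (tlen {self.tlen})"
            )
        if not 0 <= self.mapq <= 255:
            raise PafParseError(f"mapq {self.mapq} outside 0-255")
        cg = self.cigar
        if cg is None and self.cs is not None:
            cg = cs_to_cigar(self.cs)
        if cg is not None and cg.ops:
            if cg.query_consumed != self.query_span:
                raise PafParseError(
                    f"CIGAR consumes {cg.query_consumed} query bases but "
                    f"qend-qstart={self.query_span}"
                )
            if cg.target_consumed != self.target_span:
                raise PafParseError(
                    f"CIGAR consumes {cg.target_consumed} target bases but "
                    f"tend-tstart={self.target_span}"
                )
            if cg.ops[0].kind not in ALIGNED_KINDS or cg.ops[-1].kind not in ALIGNED_KINDS:
                raise PafParseError("CIGAR begins or ends with a dangling indel")

    def drop_cs(self, reason: str) -> "PafRecord":
        """Return a copy without the cs tag (used when an edit cannot keep it)."""
        if self.cs is None:
            return self
        logger.warning("dropping cs tag on %s->%s: %s", self.qname, self.tname, reason)
        return replace(
            self, cs=None, tag_order=tuple(t for t in self.tag_order if t != "cs")
        )


def parse_paf_line(line: str, line_number: int | None = None) -> PafRecord:
    """Parse one PAF line; the cg tag is normalized on the way in."""
    where = f" at line {line_number}" if line_number is not None else ""
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise PafParseError(f"expected >=12 PAF columns, got {len(cols)}{where}")
    try:
        rec = PafRecord(
            qname=cols[0],
            qlen=int(cols[1]),
            qstart=int(cols[2]),
            qend=int(cols[3]),
            strand=cols[4],
            tname=cols[5],
            tlen=int(cols[6]),
            tstart=int(cols[7]),
            tend=int(cols[8]),
            nmatch=int(cols[9]),
            alnlen=int(cols[10]),
            mapq=int(cols[11]),
        )
    except ValueError as exc:
        raise PafParseError(f"non-numeric mandatory column{where}: {exc}") from None
    order = []
    for raw in cols[12:]:
        m = _TAG_RE.match(raw)
        if m is None:
            raise PafParseError(f"malformed tag {raw!r}{where}")
        name, typ, value = m.groups()
        if name in rec.tags or name in order:
            raise PafParseError(f"duplicate tag {name}{where}")
        if name == "cg":
            rec.cigar = CigarString.parse(value)
        elif name == "cs":
            rec.cs = parse_cs(value)
        else:
            rec.tags[name] = (typ, value)
        order.append(name)
    rec.tag_order = tuple(order)
    try:
        rec.validate()
    except PafParseError as exc:
        raise PafParseError(f"{exc}{where}") from None
    return rec


def format_paf_record(rec: PafRecord) -> str:
    """Serialize a record; tags keep input order, cg/cs re-emitted from the
    (possibly modified) parsed forms."""
    cols = [
        rec.qname,
        str(rec.qlen),
        str(rec.qstart),
        str(rec.qend),
        rec.strand,
        rec.tname,
        str(rec.tlen),
        str(rec.tstart),
        str(rec.tend),
        str(rec.nmatch),
        str(rec.alnlen),
        str(rec.mapq),
    ]
    emitted = set()
    order = list(rec.tag_order)
    for name in rec.tags:
        if name not in order:
            order.append(name)
    for special in ("cg", "cs"):
        if special not in order:
            order.append(special)
    for name in order:
        if name in emitted:
            continue
        emitted.add(name)
        if name == "cg":
            if rec.cigar is not None:
                cols.append(f"cg:Z:{rec.cigar}")
        elif name == "cs":
            if rec.cs is not None:
                cols.append(f"cs:Z:{format_cs(rec.cs)}")
        elif name in rec.tags:
            typ, value = rec.tags[name]
            cols.append(f"{name}:{typ}:{value}")
    return "\t".join(cols)


def _open_text(source: Source, mode: str = "r"):
    """Accept a path, '-' (stdin/stdout), or an open text stream."""
    import sys

    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    if source == "-":
        return (sys.stdin if "r" in mode else sys.stdout), False
    return open(source, mode), True


def read_paf(source: Source) -> Iterator[PafRecord]:
    stream, close = _open_text(source)
    try:
        for i, line in enumerate(stream, 1):
            if not line.strip():
                continue
            yield parse_paf_line(line, line_number=i)
    finally:
        if close:
            stream.close()


def write_paf(records: Iterable[PafRecord], sink: Source) -> None:
    stream, close = _open_text(sink, "w")
    try:
        for rec in records:
            stream.write(format_paf_record(rec) + "\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# BED intervals


@dataclass(frozen=True)
class BedInterval:
    """A named 0-based half-open interval; extra columns kept verbatim."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise PafParseError(
                f"bad BED interval {self.chrom}:{self.start}-{self.end}"
            )


def parse_bed_line(line: str, line_number: int | None = None) -> BedInterval:
    where = f" at line {line_number}" if line_number is not None else ""
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 3:
        raise PafParseError(f"expected >=3 BED columns{where}")
    try:
        start, end = int(cols[1]), int(cols[2])
    except ValueError as exc:
        raise PafParseError(f"non-numeric BED coordinate{where}: {exc}") from None
    try:
        return BedInterval(
            chrom=cols[0],
            start=start,
            end=end,
            name=cols[3] if len(cols) > 3 else None,
            extra=tuple(cols[4:]),
        )
    except PafParseError as exc:
        raise PafParseError(f"{exc}{where}") from None


def read_bed(source: Source) -> list[BedInterval]:
    stream, close = _open_text(source)
    try:
        out = []
        for i, line in enumerate(stream, 1):
            if not line.strip() or line.startswith("#"):
                continue
            out.append(parse_bed_line(line, line_number=i))
        return out
    finally:
        if close:
            stream.close()
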