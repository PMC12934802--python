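"""Static miropeats-style ribbon rendering of identity rows as SVG.

Each stats row becomes one quadrilateral ribbon connecting its target
interval (top axis) to its query interval (bottom axis): blue for forward
alignments, orange for reverse.  Ribbon opacity encodes percent identity
(affine from the lowest displayed identity up to 100% onto [0.2, 1.0]), a
grey per-alignment identity track sits below the target axis, and optional
BED annotation tracks draw as colored blocks beside their axis.  Rendering
is pure text assembly, so identical input yields byte-identical SVG.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .paf_io import BedInterval
from .stats_filter import StatsRow

FORWARD_COLOR = "#3b6fb6"
REVERSE_COLOR = "#e07b39"
OPACITY_RANGE = (0.2, 1.0)

_WIDTH = 900
_HEIGHT = 480
_MARGIN = 50
_AXIS_GAP = 8.0
_T_AXIS_Y = 90.0
_IDENT_TRACK_Y = 100.0
_IDENT_TRACK_H = 28.0
_ANNO_H = 12.0


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")
    )


class _AxisLayout:
    """Maps (name, coordinate) to an x pixel, laying sequence names side by
    side proportionally to their displayed span."""

    def __init__(self, spans: dict[str, tuple[int, int]], width: float):
        self.spans = spans
        total = sum(hi - lo for lo, hi in spans.values())
        n = len(spans)
        usable = width - 2 * _MARGIN - _AXIS_GAP * (n - 1)
        self.scale = usable / total if total else 0.0
        self.x0: dict[str, float] = {}
        x = float(_MARGIN)
        for name, (lo, hi) in spans.items():
            self.x0[name] = x
            x += (hi - lo) * self.scale + _AXIS_GAP

    def x(self, name: str, pos: int) -> float:
        lo, hi = self.spans[name]
        pos = min(max(pos, lo), hi)
        return self.x0[name] + (pos - lo) * self.scale


def _axis_spans(pairs: Iterable[tuple[str, int, int]]) -> dict[str, tuple[int, int]]:
    spans: dict[str, tuple[int, int]] = {}
    for name, lo, hi in pairs:  # insertion order of first appearance
        if name in spans:
            spans[name] = (min(spans[name][0], lo), max(spans[name][1], hi))
        else:
            spans[name] = (lo, hi)
    return spans


def _itemrgb_color(iv: BedInterval) -> str:
    # BED9 columns after name: score, strand, thickStart, thickEnd, itemRgb
    if len(iv.extra) >= 5:
        parts = iv.extra[4].split(",")
        if len(parts) == 3:
            try:
                r, g, b = (max(0, min(255, int(p))) for p in parts)
                return f"#{r:02x}{g:02x}{b:02x}"
            except ValueError:
                pass
    return "#999999"


def render(
    rows: Sequence[StatsRow],
    target_region: Optional[BedInterval] = None,
    annotations: Sequence[tuple[str, Sequence[BedInterval], str]] = (),
    out=None,
    width: int = _WIDTH,
    height: int = _HEIGHT,
) -> str:
    """Render stats rows as an SVG document; returns the SVG text and, when
    ``out`` is given (path or stream), writes it there too.

    ``annotations`` is a sequence of (label, intervals, side) with side in
    {"target", "query"}.  ``target_region`` restricts the view to rows
    overlapping it; an empty selection raises ValueError naming the
    available target sequences.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to render")
    if target_region is not None:
        kept = [
            r
            for r in rows
            if r.tname == target_region.chrom
            and r.tstart < target_region.end
            and r.tend > target_region.start
        ]
        if not kept:
            names = ", ".join(sorted({r.tname for r in rows}))
            raise ValueError(
                f"region {target_region.chrom}:{target_region.start}-"
                f"{target_region.end} matches no row; available targets: {names}"
            )
        rows = kept

    t_spans = _axis_spans((r.tname, r.tstart, r.tend) for r in rows)
    if target_region is not None:
        lo, hi = t_spans[target_region.chrom]
        t_spans[target_region.chrom] = (
            max(lo, target_region.start),
            min(hi, target_region.end),
        )
    q_spans = _axis_spans((r.qname, r.qstart, r.qend) for r in rows)
    t_axis = _AxisLayout(t_spans, width)
    q_axis = _AxisLayout(q_spans, width)
    q_axis_y = height - 90.0

    ids = [r.perID_by_matches for r in rows]
    id_lo = min(ids)
    id_span = 100.0 - id_lo

    def opacity(ident: float) -> float:
        lo, hi = OPACITY_RANGE
        if id_span <= 0:
            return hi
        return lo + (hi - lo) * (ident - id_lo) / id_span

    svg: list[str] = []
    svg.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">'
    )
    svg.append(f'<rect width="{width}" height="{height}" fill="#ffffff"/>')

    # axes
    for axis, y, spans in (
        (t_axis, _T_AXIS_Y, t_spans),
        (q_axis, q_axis_y, q_spans),
    ):
        for name, (lo, hi) in spans.items():
            x1, x2 = axis.x(name, lo), axis.x(name, hi)
            svg.append(
                f'<line class="axis" x1="{x1:.2f}" y1="{y:.2f}" '
                f'x2="{x2:.2f}" y2="{y:.2f}" stroke="#222222" stroke-width="1.5"/>'
            )
            label_y = y - 26 if y == _T_AXIS_Y else y + 34
            svg.append(
                f'<text x="{x1:.2f}" y="{label_y:.2f}" font-family="sans-serif" '
                f'font-size="11">{_esc(name)}:{lo:,}-{hi:,}</text>'
            )

    # ribbons (row order; target edge on top)
    for i, r in enumerate(rows):
        xt1, xt2 = t_axis.x(r.tname, r.tstart), t_axis.x(r.tname, r.tend)
        xq1, xq2 = q_axis.x(r.qname, r.qstart), q_axis.x(r.qname, r.qend)
        if r.strand == "+":
            pts = [(xt1, _T_AXIS_Y), (xt2, _T_AXIS_Y), (xq2, q_axis_y), (xq1, q_axis_y)]
            color = FORWARD_COLOR
        else:  # reverse: cross the ribbon so the twist is visible
            pts = [(xt1, _T_AXIS_Y), (xt2, _T_AXIS_Y), (xq1, q_axis_y), (xq2, q_axis_y)]
            color = REVERSE_COLOR
        points = " ".join(f"{x:.2f},{y:.2f}" for x, y in pts)
        svg.append(
            f'<polygon class="ribbon" data-row="{i}" points="{points}" '
            f'fill="{color}" fill-opacity="{opacity(r.perID_by_matches):.4f}" '
            f'stroke="none"/>'
        )

    # per-alignment identity track below the target axis
    for i, r in enumerate(rows):
        xt1, xt2 = t_axis.x(r.tname, r.tstart), t_axis.x(r.tname, r.tend)
        frac = 1.0 if id_span <= 0 else (r.perID_by_matches - id_lo) / id_span
        h = max(1.0, _IDENT_TRACK_H * frac)
        svg.append(
            f'<rect class="ident" data-row="{i}" x="{xt1:.2f}" '
            f'y="{_IDENT_TRACK_Y + _IDENT_TRACK_H - h:.2f}" '
            f'width="{max(xt2 - xt1, 0.5):.2f}" height="{h:.2f}" '
            f'fill="#888888" fill-opacity="0.7"/>'
        )

    # annotation tracks: target-side above the target axis, query-side below
    # the query axis; successive tracks stack outward
    t_level = 0
    q_level = 0
    for label, intervals, side in annotations:
        if side not in ("target", "query"):
            raise ValueError(f"annotation side must be target or query, got {side!r}")
        if side == "target":
            axis, spans = t_axis, t_spans
            y = _T_AXIS_Y - 20.0 - t_level * (_ANNO_H + 4)
            t_level += 1
        else:
            axis, spans = q_axis, q_spans
            y = q_axis_y + 44.0 + q_level * (_ANNO_H + 4)
            q_level += 1
        drawn = 0
        for iv in intervals:
            if iv.chrom not in spans:
                continue
            lo, hi = spans[iv.chrom]
            if iv.end <= lo or iv.start >= hi:
                continue
            x1, x2 = axis.x(iv.chrom, iv.start), axis.x(iv.chrom, iv.end)
            svg.append(
                f'<rect class="anno" x="{x1:.2f}" y="{y:.2f}" '
                f'width="{max(x2 - x1, 0.5):.2f}" height="{_ANNO_H:.2f}" '
                f'fill="{_itemrgb_color(iv)}"/>'
            )
            drawn += 1
        svg.append(
            f'<text x="{_MARGIN - 44:.2f}" y="{y + _ANNO_H - 2:.2f}" '
            f'font-family="sans-serif" font-size="10">{_esc(label)}</text>'
        )
    svg.append("</svg>")
    doc = "\n".join(svg) + "\n"
    if out is not None:
        from .paf_io import _open_text

        stream, close = _open_text(out, "w")
        try:
            stream.write(doc)
        finally:
            if close:
                stream.close()
    return doc
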