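# Methods

This note documents the models, conventions and design decisions behind
`pafkit`, in the order the data flows: record model, coordinate engine, the
individual operations, the synthetic-data generator, and rendering.

## Record model and conventions

All coordinates are 0-based half-open (PAF/BED native). Query coordinates
always refer to the query's forward strand. CIGARs are stored in
**target-forward order** for both strands; a `-` strand record walks the
query from high to low forward-strand coordinates. This matches minimap2's
PAF emission and makes every target-space operation strand-agnostic.

A parsed record keeps the cg tag as a normalized `CigarString` (adjacent
same-kind runs merged, so normalization is idempotent by construction) and
the cs tag as a token stream. Parsing validates the full record contract:
coordinate ordering, CIGAR-consumed lengths equal to the coordinate spans,
and no dangling indel at either end of the CIGAR. `M` ops are accepted on
input but rejected with an actionable error by any identity computation,
because match/mismatch resolution requires `--eqx`-style alignments; the
error says so.

Tag handling on output: mandatory columns, then tags in input order, with
cg/cs re-serialized from the (possibly edited) parsed forms. When a record
is edited, the cs tag is trimmed in lock-step with the CIGAR by slicing the
token stream over the same alignment-column range. Two edits cannot keep a
meaningful cs cheaply — flipping query orientation (the flip is defined on
coordinates only) — there the cs is dropped with a logged warning rather
than emitted stale. Query/target inversion *does* preserve cs: insertions
and deletions swap roles, substitution base pairs swap, and on `-` strand
records token order reverses with reverse-complemented payloads.

## Coordinate engine

`aligned_columns` expands a record into per-base columns
`(tpos, qpos, kind)` in target-forward order; it is the reference
semantics, and the test suite holds every op-level routine to it.

Sub-alignment extraction (`subalignment_by_target` / `_by_query`) works in
run-length space in O(#ops): locate the first and last *aligned* (=/X)
column whose target (or forward-strand query) position falls in the
requested window, then slice the op list over that inclusive column range.
Consequences of slicing between aligned columns:

- a boundary requested inside an insertion or deletion moves inward to the
  nearest aligned base, so no output record ever starts or ends in an
  indel, and a lifted end is never extended into an insertion;
- a window that contains no aligned column (e.g. entirely inside a
  deletion) yields an explicit empty result (`None`), not an exception —
  callers skip such windows;
- `nmatch` is recomputed as the matched-base count and `alnlen` as the
  total column count of the sliced CIGAR; `mapq` and other tags carry
  through unchanged.

## Overlap trimming (`trim-paf`)

Overlaps are query-coordinate intersections between records sharing a query
name, discovered over all pairs and processed largest-first (recomputed
after every trim, since spans change; ties keep input order). For one pair,
per-base scores over the overlap window are: match → `+1`, mismatch → `-1`,
insertion base → `-1` (each at its own query position); deletion bases
consume no query, so their penalty attaches to the query position of the
next aligned column in the target-forward walk — which means a split can
never land inside a deletion. The optimal split p\* maximizes the left
record's cumulative score before p plus the right record's after p,
computed with prefix/suffix sums over the window; ties break to the
smallest coordinate for determinism. Defaults (+1/−1/−1) are exposed as CLI
flags; a single per-base indel score is used rather than separate gap
open/extend.

The left record (smaller query start) is trimmed to end at p\*, the right
to start at p\*. When the right record is *contained* in the left, the
left record's portion past the overlap survives as a separate piece — the
two-boundary-split resolution — rather than being silently discarded;
pieces that retain no aligned column are dropped. Iteration terminates
because total pairwise overlap strictly decreases every round, and the
result is idempotent: a second pass finds no overlaps.

## SV splitting (`break-paf`)

Records are cut at every I/D op **strictly** longer than the threshold
("exceeding"); the oversized op appears in no output segment. Segment edges
then shrink to aligned columns, so a sub-threshold indel left dangling at a
cut edge is also trimmed (its bases become unaligned). Segments inherit
name/mapq, are tagged `id:Z:{record}.{segment}` for provenance, and conserve
the input's aligned columns exactly. Only single ops trigger cuts; runs of
mixed adjacent indels that sum over the threshold do not.

## Orientation and scaffolding

`orient` sums query-consuming aligned bases per query name by strand and
flips every record of a query only when reverse strictly exceeds forward;
exact ties keep the original orientation (determinism over arbitrary
flipping), and contigs are not renamed. `scaffold` assigns each query
wholly to the target with most of its aligned bases (ties to the
lexicographically smallest target name), orders contigs by minimum target
start (ties by query name), and offsets coordinates into a
`{tname}_scaffold` coordinate system with a configurable unaligned gap
(default 1,000 bases) between consecutive contigs; the original name is
kept in a `qn:Z:` tag. CIGARs are untouched, so identity statistics are
preserved bit-exactly.

## Identity statistics

Three identity flavors differ only in denominator, matching the three
columns of the BED dialect the plotter consumes: substitutions only
(`by_matches`), plus gap events (`by_events`), plus gap bases (`by_all`).
The denominators nest, so the three values are non-increasing in that
order, and all three equal 100 exactly when there are no mismatches and no
gap bases. A degenerate record with no aligned column emits a zero row with
a warning instead of aborting a stream. Percentages print with four
decimals for stable text diffs. `filter --paired-len` groups records by
(query, target) pair and keeps the group iff its summed alignment block
length reaches the threshold.

## Synthetic-data generator

The generator plants non-overlapping events on a random ACGT target and
emits the records a faithful `--eqx` aligner would produce, with the cs
tags and sequences realized consistently (the FASTA pair can be written for
end-to-end runs through a real aligner, though no test requires one):

- substitution regions draw each base independently at the given rate and
  record every realized position, making mismatch counts exact, not
  expected values;
- a tandem duplication is modelled as two identical target copies against a
  single query copy, which is precisely the configuration that produces two
  records overlapping in query coordinates by the unit length;
- an inversion produces a `-` strand record flanked by `+` records, with
  orientation flipped exactly inside the event in the truth map;
- insertions/deletions become single I/D ops; inserted bases are novel and
  absent from the truth map.

Structural events must start at target position ≥ 1, end before the last
base, and be separated by at least one unaffected base — this guarantees by
construction that every record begins and ends on an aligned column. The
truth map stores one (target, query, orientation) triple per homologous
base pair. Randomized scenarios (`random_svspecs`) place events left to
right with random gaps; indel lengths are log-uniform on [1, max] so both
single-base and near-threshold events occur.

What the generator does *not* emulate: alignment artifacts (soft clipping,
mapq degradation, split inversions with micro-homology), repeat-induced
mis-mapping, and aligner-specific tie-breaking at SV boundaries. Passing
tests therefore demonstrate that the *operations* are exact on well-formed
records, not that any aligner's output is well-formed.

Problem sizes used by the test suite and the acceptance script — 500 random
alignments (30-kb targets, indels up to 10 kb) for the projection oracle,
200 duplication/containment fixtures for trimming, 100 fixtures for
orientation, and a single 1-Mb fixture for the end-to-end pipeline — were
chosen so each property is exercised across all event types at desk scale.

## Rendering

The plotter lays sequence names side by side on each axis proportionally to
their displayed spans, draws one quadrilateral ribbon per row (crossed for
`-` strand so the twist is visible), and maps identity to opacity affinely
from the minimum displayed `perID_by_matches` up to 100% onto [0.2, 1.0]
(when all rows share one identity, opacity is 1.0). Colors are fixed:
`#3b6fb6` forward, `#e07b39` reverse. A grey per-alignment identity track
sits below the target axis; annotation intervals draw as blocks beside
their axis, honoring BED9 `itemRgb` when present. Output is assembled as
plain text with fixed float formatting, so identical input produces
byte-identical SVG. Interactivity (zoom, selection, shared views) is out of
scope by design — the renderer targets publication-style static figures.

## Known limitations

- Multi-hop liftover (through two alignments) and chain files are not
  supported; intervals project through single records independently.
- `trim-paf` optimizes each overlap pair greedily (largest first); it does
  not search globally over all records' split points jointly.
- Scaffolding emits no FASTA/AGP; it only rewrites coordinates.
- BAM input is not parsed; convert to PAF (e.g. `paftools.js sam2paf`)
  first.
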