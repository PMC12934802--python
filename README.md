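# pafkit

CIGAR-aware surgery on pairwise alignments in PAF format.

Whole-genome alignment of modern assemblies (T2T genomes, pangenome
contigs) is routine, but the raw minimap2 output is awkward at exactly the
loci people care about: at segmental duplications and inversion boundaries,
supplemental alignments map the *same query bases* to several target
positions, inflating coverage, confounding breakpoints and double-counting
identity. `pafkit` is a toolkit of small, pipe-composable operations that
edit PAF records while keeping every CIGAR exactly consistent with the
record's coordinates, so identity statistics computed after any edit remain
exact:

- **`liftover`** — project BED intervals through alignments; the output is a
  *trimmed PAF record* with a CIGAR spanning exactly the lifted region (not
  just coordinates), so it pipes straight into `stats`. A lifted end is never
  extended into an insertion: it stops at the last aligned base.
- **`trim-paf`** — resolve overlapping query alignments by cumulative-score
  maximization: for each overlap, find the split point p\* maximizing
  F_left(p) + S_right(p), the summed per-base scores (match +1, mismatch −1,
  indel base −1 by default) of the left record before p and the right record
  after p; iterate from the largest overlap until no query base is aligned
  more than once.
- **`break-paf`** — split records at insertions/deletions exceeding a length
  threshold (e.g. `-m 5000`), turning SV-spanning alignments into
  fine-grained segments.
- **`orient`** / **`--scaffold`** — flip query contigs to majority-forward
  orientation and optionally merge them into per-target pseudo-scaffolds
  ordered by target position.
- **`stats`** — per-alignment identity rows straight from the CIGAR:
  perID_by_matches = 100·m/(m+x), perID_by_events = 100·m/(m+x+gap events),
  perID_by_all = 100·m/(m+x+gap bases).
- **`filter`**, **`invert`** — paired-length filtering and query/target
  swapping.
- **`plot`** — a static miropeats-style SVG: ribbons connect target and
  query axes, blue for forward and orange for reverse alignments, opacity
  encoding percent identity, with optional BED annotation tracks.
- **`fixtures`** — a deterministic generator that plants duplications,
  inversions, substitutions and large indels on a toy genome and emits the
  PAF records plus a base-level truth map, so everything above can be tested
  against an exact oracle without any external data.

## Worked example

Plant a 1%-substitution region, a 400-bp tandem duplication and a 6-kb
deletion on a 20-kb toy target, then run the standard pipeline:

```sh
pafkit fixtures --target-len 20000 \
    --sv SUB:1000:8000:0.01 --sv DUP:10000:400 --sv DEL:12000:6000 \
    --seed 11 --out-prefix demo
pafkit trim-paf demo.paf | pafkit break-paf -m 5000 \
    | pafkit orient | pafkit stats --paf | cut -f1-11
```

```
#tname	tstart	tend	qname	qstart	qend	strand	perID_by_matches	perID_by_events	perID_by_all	matches
tgt	0	10000	qry	0	10000	+	99.3100	99.3100	99.3100	9931
tgt	10400	12000	qry	10000	11600	+	100.0000	100.0000	100.0000	1600
tgt	18000	20000	qry	11600	13600	+	100.0000	100.0000	100.0000	2000
```

Reading the rows: the duplication made the single query copy align to both
target copies, overlapping in query coordinates; `trim-paf` split the
overlap at query position 10,000, so the first row ends there and no query
base is counted twice. The 99.31% identity of the first row is exactly the
realized substitution count over its 10,000 aligned bases. `break-paf`
removed the 6-kb deletion (an op longer than 5,000 bases), which is why the
target jumps from 12,000 to 18,000 between the last two rows while the
query stays contiguous. Piping the full table into
`pafkit plot --bed - -o demo.svg` draws one blue ribbon per row.

Lifting gene annotations through an alignment and scoring each gene is one
pipe:

```sh
pafkit liftover --bed genes.bed aln.paf | pafkit stats --paf
```

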