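# Methods

This note records the models, conventions and numerical choices behind
genoviz, the parameters that matter, what the synthetic-data generator does
and does not emulate, and the places where the design was genuinely open.

## Coordinate conventions

All internal coordinates are **1-based closed** intervals on named
sequences; a single base is `[p, p]` with width 1.  The 0-based half-open
dialect exists only at I/O boundaries: BED input is shifted on read
(`start+1`), `convert_dialect` is its own inverse, and widths are preserved
in both directions.  Strand is `+`, `-` or `*` (unstranded) and never
affects interval algebra — it only feeds aesthetics (gene-model color,
arrow-rect direction).

Grouping flattens the nested "list of range sets" idea into one table plus
a group-key column (`tx_id` for transcripts, `qname` for reads).  Interval
algebra on groups is **per group**: `gaps_within_groups` returns, for each
group independently, the complement of the union of its members within the
group's hull.  When two transcripts interleave on one chromosome each still
gets its own introns — the semantics a gene-model plot needs.  Abutting
members merge, so no zero-width gaps are ever emitted.

## Stepping

The stepping stat assigns integer display levels so overlapping units
stack.  No standard algorithm is mandated by the figure style, so genoviz
fixes a deterministic greedy first-fit: units (rows, or group hulls when
grouped) are sorted by (start, longer-width-first, input order) and each
takes the smallest level whose previously placed unit ends at least
`min_gap + 1` bp before it.  For interval graphs this greedy coloring is
optimal, giving the invariant *max level = max per-base depth* when
`min_gap = 0` — which the tests verify against a brute-force coverage
oracle.  `min_gap` (default 0 bp) is exposed because dense read tracks
need visual separation.  Packing is independent per seqname.

## Coverage, windows, pileup

Coverage is computed by event counting (+1 at starts, −1 one past ends)
and stored run-length encoded; runs are sorted, abutting, tile the window
exactly, and adjacent runs always differ in depth.  The conservation
identity Σ depth·width = Σ interval widths holds exactly and is asserted
in tests.  The default window is the data hull; explicit windows pad with
zero-depth runs and clip.

Sliding-window aggregation (`stat_aggregate`) uses **row-count** windows —
k consecutive rows per seqname in (seqname, start) order, advancing by
`step`, incomplete trailing windows dropped — matching the "windows of
five consecutive SNPs" use case; base-pair windows are out of scope.  The
window interval reported is (first row's start, max end among the window's
rows), identical to "first start, last end" for point inputs like SNPs.

The mismatch pileup consumes CIGAR-projected alignment blocks.  Only
M/=/X positions contribute depth: insertions have no reference position,
and deletions (D) and splice skips (N) split blocks, so no query base is
ever tallied over a reference position the read does not cover.  Per
position, a query base equal to the reference (both in A/C/G/T) increments
`match_count`; anything else increments its letter's mismatch column, with
all non-ACGT codes pooled under N and never counted as matches.  Hence
`match + A + C + G + T + N = depth` everywhere, which equals the coverage
of the M-blocks — both identities are tested.  There is no base-quality
weighting and no per-strand split.

CIGAR projection itself: M/=/X consume query and reference; D/N reference
only; I/S query only; H/P neither.  Each M/=/X run becomes its own block
(so I splits blocks too); pysam's `get_blocks` (which merges around
insertions) serves as an independent oracle in the tests after merging
abutting blocks on both sides.

## Coordinate transforms

**Genome concatenation.**  Each chromosome gets an (offset, scale) with
`x = offset + pos·scale`; plot units are 1-based like genomic units, so
the first base of the first chromosome maps to 1.  Proportional mode uses
scale 1 everywhere; uniform mode stretches every chromosome onto
`uniform_width` units, defaulting to the longest chromosome's length so
the longest chromosome is unscaled.  A buffer ≥ 0 separates consecutive
images.  The inverse is exact on chromosome images (`pos =
ceil((x − offset)/scale)` with a 1e-9 guard against float dust) and
returns a gap marker inside buffers; round-trip identity over random loci
is property-tested in all four mode×buffer combinations.

**Gap truncation.**  The keep-set is merged first; kept intervals map at
scale 1 with their widths preserved *exactly* (integer image grid), and
each gap maps onto an image of exactly `gap_width` plot units (default:
1% of the total kept span).  A `proportional` gap policy is also provided
(same total gap image span, shared among gaps proportionally to their
source widths); `fixed` is the default.  Forward-mapping a position inside
a truncated gap returns the gap image's midpoint — needed when features
straddle gap edges — while the inverse there returns a gap marker.  An
optional context hull adds flanking gap segments so features just outside
the keep-set remain mappable.

In the rendering pipeline, geoms emit data-space primitives and the
coordinate transform is applied afterwards — with one asymmetry: gap
truncation is a pure x→x map on a single chromosome and is applied
renderer-side, while genome concatenation needs seqnames that primitives
do not carry, so multi-chromosome (Manhattan) plots are built directly in
global coordinates at layer-construction time.

## Layouts

Linear layout facets implicitly by chromosome, one panel per seqname in
SeqInfo order (else first appearance); an explicit window overrides the
panel's x-domain.  Karyogram panels fill a row-major grid with page widths
proportional to chromosome length relative to the longest (tested to 1e-9
relative).  `facet_by_ranges` assigns rows to every labelled range they
overlap, so straddling rows appear in several panels.

Circular layout uses compass angles (0° at 12 o'clock) and clockwise
direction by default, with a 5° default gap between chromosome arcs; on a
full circle a closing gap follows the last chromosome so spans plus gaps
sum to exactly 360°.  Arc spans are proportional to the genome map's image
widths, so a uniform map gives equal arcs.  Within a chromosome the
angular fraction of base `pos` is `pos/length` (the base's right edge):
this makes the no-gap unit examples exact (`global = span ⇒ angle =
total degrees`) at the cost of the first base sitting `span/length`
degrees inside its arc; the exact-gap property is therefore stated — and
tested — at the arc-boundary level, where it holds identically.  Links are
quadratic Béziers between points on the link ring's inner radius with the
control point at `curvature·inner_radius` (default 0.2) from the centre
along the chord-midpoint direction; curvature 0 routes antipodal links
through the exact centre.  Intra/inter classification is seqname equality.

## Geoms: sizes and palettes

Arrow-rect notch defaults to 2% of the data hull width.  Chevron apex
offset defaults to 0.25 level units.  Arch apex height is exactly
`height_scale·span` (control point at twice that, since a quadratic Bézier
reaches half its control height); stroke width is `max(floor, sqrt(count))`
with floor 0.5 so zero-count junctions remain visible.  The coverage-area
polygon uses run edges at `start−0.5`/`end+0.5` so its geometric area
equals the covered-base count.  Mismatch bars stack match-gray then A, C,
G, T, N, omitting zero-height segments.  The categorical palette is the
fixed Okabe–Ito colorblind-safe list; strand colors are blue (+), vermilion
(−), gray (*); ideogram fills follow the Giemsa convention from white
(gneg) through grays to black (gpos100), with centromeric bands as red
triangles.  Edge-link slots are laid over the data hull (slot width =
hull/n) so connectors can end at true genomic coordinates on the same axis.

## Composition and rendering

`PlotSpec` is immutable; `+` returns a new spec (layers append, coord and
theme replace), so saved plots can be re-themed.  `autoplot` dispatches on
the data type through a documented registry; the grouped-range builder and
the low-level arrowrect+chevron layers share the same stepping and geom
code paths, which is what makes the two routes produce identical primitive
lists — asserted element-by-element in the tests.  `theme_null()` switches
off background, axis labels and legend.

The SVG renderer is a pure function of the spec: fixed float formatting
(three decimals, trailing zeros stripped), fixed attribute order, and no
unordered iteration, giving byte-identical output for identical specs.
Each primitive becomes exactly one element with `class` (geom name) and
`data-group` (originating row/group id); decoration carries no
`data-group`.  Primitives are clipped to the panel x-domain by clamping
(degenerate shapes at the edge rather than geometric re-tessellation — a
deliberate simplification).  Track stacks allocate page bands in the ratio
of their heights and force one shared x-domain on every member; zooming
and shifting replace that domain without touching member primitives.

## Synthetic data

The generator emulates an RNA-seq-like scenario at desk scale: two ~60 kb
chromosomes; four transcripts of 4–7 exons (exons 80–300 bp, introns
200–1500 bp) laid out with partial overlap on chr1; 300 spliced 75 bp
reads sampled uniformly over transcript coordinates with `xMyNzM` CIGARs;
six mismatch sites planted by mutating *every* covering read, so the
recorded multiplicity equals the coverage depth at the site; plus feature,
link, score and cytoband tables.  Randomness comes from one seeded numpy
generator and files are written with stable ordering, so equal specs give
byte-identical directories.  Not emulated: sequencing-error noise beyond
the planted sites, base qualities, paired ends, strand-specific protocols,
indel-containing reads, and non-uniform expression.  Passing tests
therefore demonstrate the correctness of the statistics and transforms on
clean, fully-known inputs — not robustness to the pathologies of real
libraries.

Problem sizes in the test suite and acceptance script (200 random interval
sets for stepping, 10 coverage fixtures over 100 kb windows, 1000 loci per
coordinate-map configuration, 200 random links and CIGARs) were chosen to
exercise the oracles thoroughly while keeping the whole suite in the
seconds-to-a-minute range.

## Known limitations

No VCF/2bit/BAM-binary input (SAM text is the supported alignment
dialect; an indexed-BAM adapter would slot in at `read_sam` without
touching the stats).  No interactive output, no raster export, no log/sqrt
axis scales, no text layout beyond anchored labels, and no karyotype-aware
chromosome reordering — layouts follow SeqInfo order.  Legends list
distinct mapped values with swatches; there is no full guide system.
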