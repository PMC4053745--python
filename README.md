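# genoviz

A grammar-of-graphics toolkit for genomic interval data, written for
bioinformaticians who want genome-browser-style figures — gene models,
coverage tracks, splice summaries, Manhattan plots, karyograms, circular
link plots — built from composable parts and rendered to deterministic SVG.

The unifying trait of genomic data is that everything occupies ranges on a
genome: gene annotations, read alignments, variant scores.  genoviz treats
the range table as the universal currency and extends the grammar of
graphics (data → stat → geom → coord → layout) with the biological pieces
that conventional plotting grammars lack:

* **stats** — *stepping* (assign integer display levels `y` so overlapping
  intervals stack instead of overplotting: greedy first-fit over intervals
  sorted by start, which is level-optimal for interval graphs, so
  `max level = max per-base depth`); per-base *coverage*
  `d(p) = #{i : s_i ≤ p ≤ e_i}` stored run-length encoded; sliding-window
  aggregation over k consecutive rows; and a *mismatch pileup* that splits
  each reference position's depth into matches and per-nucleotide
  mismatches.
* **coords** — invertible piecewise-linear maps `x = offset_c + pos·scale_c`
  that concatenate chromosomes onto one axis (proportional or uniform
  scaling, optional inter-chromosome buffer), and a *gap-truncation* map
  that keeps exons at scale 1 while compressing every intron onto a small
  fixed image width.
* **layouts** — linear (implicit facet by chromosome), karyogram
  (length-scaled chromosome array), and circular (arcs with exact
  inter-chromosome gaps; links as quadratic Béziers, intra- vs
  inter-chromosomal classified by seqname).
* **geoms** — rect/arrow-rect, chevron (introns), alignment (connected
  exon+intron glyphs per transcript), arch (splice junctions, apex height
  proportional to span, stroke width ∝ √count), coverage area, stacked
  mismatch bars, edge-links, and Giemsa-stained ideograms.
* **composition** — `autoplot(data)` recognises the data structure and
  builds the right plot; the low-level API composes the same layers
  explicitly with `+`; `tracks([...], heights=[4,1,1])` stacks plots over
  one shared genomic axis with zoom/shift.

Everything renders through one SVG backend in which every drawing primitive
becomes exactly one SVG element tagged with its originating row/group id,
so outputs are machine-checkable and byte-reproducible.

A deterministic synthetic-data generator (`genoviz.simulate`) emulates
multi-exon transcripts, spliced short reads with planted mismatches and
junction counts, score tables, cytobands and link tables — with a full
ground-truth table — so none of the examples or tests need external data.

## Worked example

The classic gene-model figure: ten exons of two X-linked transcript
isoforms, grouped by transcript id.

```python
import genoviz as gv

exons = gv.make_range_table(
    [("chrX", 48242968, 48243005, "+"), ("chrX", 48243475, 48243563, "+"),
     ("chrX", 48244003, 48244117, "+"), ("chrX", 48244794, 48244889, "+"),
     ("chrX", 48246753, 48246802, "+"), ("chrX", 48270193, 48270307, "-"),
     ("chrX", 48269421, 48269516, "-"), ("chrX", 48267508, 48267557, "-"),
     ("chrX", 48262894, 48262998, "-"), ("chrX", 48261524, 48262111, "-")],
    metadata={"tx_id": ["35775"] * 5 + ["35778"] * 5},
    group_key="tx_id",
)
plot = gv.autoplot(exons, gv.aes(color="strand"))
gv.render_svg(plot, "gene_model.svg")
```

Running `python examples/gene_model.py` prints:

```
10 exons in 2 transcripts; 8 introns
first intron of tx 35775: [48243006, 48243474] (the complement of the exon union within the transcript hull)
gene_model.svg: 10 exon rectangles, 8 intron chevrons
stepping put both transcripts on level 1 because their hulls do not overlap; overlapping isoforms would stack on separate levels
```

The 8 introns are computed per transcript as the complement of the exon
union within each transcript's hull; each gets a chevron glyph on its
transcript's stepping level, colored by strand like the exons.  The same
figure can be built explicitly — `gv.empty_plot(exons) +
gv.layer_arrowrect() + gv.layer_chevron(gv.gaps_within_groups(exons))`
produces the identical primitive list.

The other capabilities each have a narrative script under `examples/`
(splice summary tracks with gap truncation, mismatch pileup, Manhattan,
karyogram, circular links, edge-linked exons), and a thin CLI wraps the
common figures:

```sh
genoviz simulate --seed 1 --outdir demo/
genoviz gene-model --gff demo/genes.gff3 --gene tx_id=tx1 \
    --coord truncate-gaps --gap-width 10 --out gene.svg
genoviz circular --chromsizes sizes.tsv --links demo/links.tsv --out circ.svg
```

## File formats

BED (0-based half-open, converted on read), GFF3/GTF (1-based closed;
`Parent`/`transcript_id` become the `tx_id` grouping column), SAM text
(CIGAR projected to reference blocks; no index needed), FASTA, and TSV
dialects for chromosome sizes (`name\tlength`, headerless), links
(`chr1 pos1 chr2 pos2 score support`), scores (`chr pos value [group]`)
and cytobands (`chrom start end name gieStain`).  Readers reject malformed
records with line-numbered errors.

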