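"""Gene-model plot: exons as rectangles, introns as chevrons, stacked by
stepping levels, colored by strand.

Builds the two-isoform worked example inline, lets autoplot recognise the
grouped range table, and renders the figure to SVG.
"""

import genoviz as gv

EXONS = [
    ("chrX", 48242968, 48243005, "+", "35775"),
    ("chrX", 48243475, 48243563, "+", "35775"),
    ("chrX", 48244003, 48244117, "+", "35775"),
    ("chrX", 48244794, 48244889, "+", "35775"),
    ("chrX", 48246753, 48246802, "+", "35775"),
    ("chrX", 48270193, 48270307, "-", "35778"),
    ("chrX", 48269421, 48269516, "-", "35778"),
    ("chrX", 48267508, 48267557, "-", "35778"),
    ("chrX", 48262894, 48262998, "-", "35778"),
    ("chrX", 48261524, 48262111, "-", "35778"),
]

transcripts = gv.make_range_table(
    [r[:4] for r in EXONS],
    metadata={"tx_id": [r[4] for r in EXONS]},
    group_key="tx_id",
)

gaps = gv.gaps_within_groups(transcripts)
print(f"{len(transcripts)} exons in {len(set(transcripts.column('tx_id')))} "
      f"transcripts; {len(gaps)} introns")
first = gaps.df.iloc[0]
print(f"first intron of tx 35775: [{first['start']}, {first['end']}] "
      f"(the complement of the exon union within the transcript hull)")

plot = gv.autoplot(transcripts, gv.aes(color="strand"))
doc = gv.render_svg(plot, "gene_model.svg")
n_rects = doc.count('class="range"')
n_chevrons = doc.count('class="chevron"')
print(f"gene_model.svg: {n_rects} exon rectangles, {n_chevrons} intron chevrons")
print("stepping put both transcripts on level 1 because their hulls do not "
      "overlap; overlapping isoforms would stack on separate levels")
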