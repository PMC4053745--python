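"""Splice summary as stacked tracks with the gap-truncation coordinate.

Simulates spliced RNA-seq reads over multi-exon transcripts, then stacks
three tracks sharing one x axis: junction arches (stroke width encodes the
junction read count), the read-coverage area, and the gene models.  The
gap-truncation transform shrinks the introns so exonic detail fills the
page even though the whole gene region is in view.
"""

import tempfile
from pathlib import Path

import genoviz as gv
from genoviz.simulate import FixtureSpec, generate_fixture

with tempfile.TemporaryDirectory() as tmp:
    fx = generate_fixture(FixtureSpec(seed=7), Path(tmp))
    aln = gv.read_sam(fx["sam"])
    genes = gv.read_features(fx["gff3"], "gff3")

exons = genes.subset(genes.df["type"].to_numpy() == "exon")
junctions = gv.stat_junctions(aln)
coverage = gv.stat_coverage(aln.blocks_table(group_by_read=False))

print(f"{len(aln)} reads, {len(junctions)} distinct splice junctions, "
      f"max coverage depth {coverage.max_depth}")
top = junctions.df.nlargest(1, "count").iloc[0]
print(f"best-supported junction: [{top['start']}, {top['end']}] "
      f"with {top['count']} spanning reads")

tmap = gv.build_truncate_map(gv.reduce_ranges(exons), gap_width=50)
coord = gv.coord_truncate_gaps(tmap)
stack = gv.tracks(
    [
        gv.empty_plot(junctions) + gv.layer_arch() + coord,
        gv.empty_plot(coverage) + gv.layer_area() + coord,
        gv.autoplot(exons, gv.aes(color="strand")) + coord,
    ],
    heights=[2, 1, 1],
)
gv.render_svg(stack, "splice_summary.svg")
dom = tmap.domain
print(f"splice_summary.svg: genomic domain [{dom[0]}, {dom[1]}] compressed "
      f"onto {tmap.image_span:.0f} plot units (introns -> 50 units each)")
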