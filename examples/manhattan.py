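"""Grand linear (Manhattan) view: all chromosomes on one x axis.

Simulates a per-position score table with three analysis methods, smooths
the values over sliding windows of five consecutive positions, concatenates
the chromosomes with the genome coordinate map, and facets one panel per
method.  Alternating point colors mark the chromosome boundaries.
"""

import tempfile
from pathlib import Path

import genoviz as gv
from genoviz.simulate import FixtureSpec, generate_fixture

with tempfile.TemporaryDirectory() as tmp:
    fx = generate_fixture(FixtureSpec(seed=3), Path(tmp))
    scores = gv.read_table(fx["scores"], "scores")

seqinfo = gv.SeqInfo((("chr1", 60000), ("chr2", 60000)))
gmap = gv.build_genome_map(seqinfo, mode="proportional", buffer=2000)
print(f"{len(scores)} score rows on {len(seqinfo)} chromosomes; "
      f"global axis spans {gmap.total_span:.0f} plot units "
      f"(chr2 starts at {gv.genome_to_global(gmap, ('chr2', 1)):.0f})")

plot = gv.manhattan_plot(scores, seqinfo, buffer=2000, k=5, stat="mean")
gv.render_svg(plot, "manhattan.svg", page=(900, 500))
n_groups = scores["group"].nunique()
n_windows = len(scores) // n_groups - (5 - 1) * len(seqinfo)
print(f"manhattan.svg: {n_groups} facet panels, ~{n_windows} windowed points "
      "each; each point is the mean score of 5 consecutive positions")
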