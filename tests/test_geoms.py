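"""Geoms: data → drawing primitives."""

import numpy as np
import pytest

import genoviz as gv
from genoviz.geoms import (
    BASE_COLORS,
    STAIN_COLORS,
    geom_edge_links,
    geom_ideogram,
    geom_mismatch_bars,
)
from genoviz.io import AlignmentTable, ReadAlignment, cigar_reference_blocks
from genoviz.ranges import GenomicRange
from genoviz.stats import stat_coverage, stat_mismatch


def _shoelace(points):
    area = 0.0
    n = len(points)
    for i in range(n):
        x1, y1 = points[i]
        x2, y2 = points[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


class TestGeomRect:
    def test_exon_rects_span_exact_coordinates(self, transcripts):
        sub = transcripts.subset(transcripts.df["tx_id"].to_numpy() == "35775")
        prims = gv.geom_rect(sub, y=1.0)
        assert len(prims) == 5
        for p, (s, e) in zip(prims, zip(sub.starts, sub.ends)):
            (x1, _), (x2, _) = p.points
            assert (x1, x2) == (s, e)

    def test_unstranded_arrow_falls_back_to_rect(self):
        t = gv.make_range_table([("chr1", 10, 20, "*")])
        (p,) = gv.geom_rect(t, shape="arrow")
        assert p.kind == "rect"

    def test_arrow_polygon_vertices(self):
        t = gv.make_range_table([("chr1", 100, 200, "+")])
        (p,) = gv.geom_rect(t, shape="arrow", notch=5.0, y=0.0)
        xs = [x for x, _ in p.points]
        assert max(xs) == 205.0  # rightmost vertex at end + notch
        assert min(xs) == 100.0
        t = gv.make_range_table([("chr1", 100, 200, "-")])
        (p,) = gv.geom_rect(t, shape="arrow", notch=5.0, y=0.0)
        xs = [x for x, _ in p.points]
        assert min(xs) == 95.0 and max(xs) == 200.0

    def test_strand_mapped_to_color(self, transcripts):
        prims = gv.geom_rect(transcripts, gv.aes(color="strand"), y=1.0)
        fills = {p.aes["fill"] for p in prims}
        assert len(fills) == 2

    def test_unresolvable_aesthetic_rejected(self, transcripts):
        with pytest.raises(KeyError, match="nope"):
            gv.geom_rect(transcripts, gv.aes(color="nope"))


class TestGeomChevron:
    def test_apex_at_midpoint(self):
        t = gv.make_range_table([("chrX", 48243006, 48243474)])
        (p,) = gv.geom_chevron(t, y=1.0, apex_offset=0.25)
        assert p.points[1] == (48243240.0, 1.25)

    def test_zero_offset_is_straight(self):
        t = gv.make_range_table([("chr1", 10, 20)])
        (p,) = gv.geom_chevron(t, y=2.0, apex_offset=0.0)
        assert {y for _, y in p.points} == {2.0}

    def test_one_chevron_per_gap(self, transcripts):
        gaps = gv.gaps_within_groups(transcripts)
        sub = gaps.subset(gaps.df["tx_id"].to_numpy() == "35775")
        assert len(gv.geom_chevron(sub, y=1.0)) == 4


class TestGeomAlignment:
    def test_counts_members_plus_gaps(self, transcripts):
        prims = gv.geom_alignment(transcripts)
        rects = [p for p in prims if p.aes.get("class") == "range"]
        chevrons = [p for p in prims if p.aes.get("class") == "chevron"]
        assert len(rects) == 10 and len(chevrons) == 8

    def test_single_exon_group(self):
        t = gv.make_range_table(
            [("chr1", 5, 25)], metadata={"tx_id": ["t"]}, group_key="tx_id"
        )
        prims = gv.geom_alignment(t)
        assert len(prims) == 1 and prims[0].kind == "rect"

    def test_member_level_equals_group_level(self, transcripts):
        prims = gv.geom_alignment(transcripts)
        by_group = {}
        for p in prims:
            ys = sorted({round((p.points[0][1] + p.points[-1][1]) / 2, 6)}
                        ) if p.kind != "rect" else [
                round((p.points[0][1] + p.points[1][1]) / 2, 6)
            ]
            by_group.setdefault(p.group, set()).update(ys)
        for levels in by_group.values():
            assert len(levels) == 1

    def test_random_fixture_counts(self):
        rng = np.random.default_rng(31)
        recs, gids = [], []
        for g in range(6):
            n = int(rng.integers(1, 6))
            pos = int(rng.integers(1, 10000))
            for _ in range(n):
                w = int(rng.integers(5, 50))
                recs.append(("chr1", pos, pos + w))
                gids.append(f"g{g}")
                pos += w + int(rng.integers(2, 100))
        t = gv.make_range_table(recs, metadata={"tx_id": gids}, group_key="tx_id")
        prims = gv.geom_alignment(t)
        expected = len(t) + len(gv.gaps_within_groups(t))
        assert len(prims) == expected


class TestGeomArch:
    def test_apex_height_proportional_to_span(self):
        t = gv.make_range_table(
            [("chr1", 100, 200), ("chr1", 300, 500)], metadata={"count": [3, 5]}
        )
        p1, p2 = gv.geom_arch(t, height_scale=0.3, base=0.0)
        # quadratic Bezier apex = half the control height
        apex1 = p1.points[1][1] / 2.0
        apex2 = p2.points[1][1] / 2.0
        assert apex1 == pytest.approx(30.0)
        assert apex2 / apex1 == pytest.approx(2.0)

    def test_zero_count_still_drawn_with_floor(self):
        t = gv.make_range_table([("chr1", 1, 100)], metadata={"count": [0]})
        (p,) = gv.geom_arch(t, size_floor=0.5)
        assert p.aes["size"] == 0.5

    def test_size_is_sqrt_of_count(self):
        t = gv.make_range_table([("chr1", 1, 100)], metadata={"count": [16]})
        (p,) = gv.geom_arch(t)
        assert p.aes["size"] == pytest.approx(4.0)


class TestGeomCoverageArea:
    def test_step_polygon_area_equals_covered_bases(self):
        t = gv.make_range_table([("chr1", 1, 5), ("chr1", 3, 7)])
        cov = stat_coverage(t, window=GenomicRange("chr1", 1, 7))
        (p,) = gv.geom_coverage_area(cov)
        assert p.kind == "polygon"
        assert _shoelace(p.points) == pytest.approx(cov.total) == 10.0

    def test_vertices_nondecreasing_x(self):
        t = gv.make_range_table([("chr1", 2, 9), ("chr1", 5, 30), ("chr1", 18, 21)])
        cov = stat_coverage(t)
        (p,) = gv.geom_coverage_area(cov)
        xs = [x for x, _ in p.points]
        assert all(b >= a for a, b in zip(xs, xs[1:]))

    def test_all_zero_coverage_degenerate_baseline(self):
        cov = stat_coverage(
            gv.make_range_table([]), window=GenomicRange("chr1", 1, 10)
        )
        (p,) = gv.geom_coverage_area(cov)
        assert {y for _, y in p.points} == {0.0}


class TestGeomMismatchBars:
    def _mm(self):
        read = ReadAlignment(
            qname="r", flag=0, seqname="chrT", pos=1, cigar="8M",
            seq="ACGAACGT", blocks=tuple(cigar_reference_blocks(1, "8M")),
        )
        return stat_mismatch(
            AlignmentTable([read]), {"chrT": "ACGTACGT"},
            GenomicRange("chrT", 1, 8),
        )

    def test_mismatch_position_single_colored_segment(self):
        prims = geom_mismatch_bars(self._mm())
        at4 = [p for p in prims if p.group == 4]
        assert len(at4) == 1
        assert at4[0].aes["fill"] == BASE_COLORS["A"]

    def test_match_positions_single_neutral_segment(self):
        prims = geom_mismatch_bars(self._mm())
        at1 = [p for p in prims if p.group == 1]
        assert len(at1) == 1 and at1[0].aes["class"] == "mismatch-match"

    def test_segment_heights_sum_to_depth(self):
        mm = self._mm()
        prims = geom_mismatch_bars(mm)
        for pos, depth in zip(mm.df["pos"], mm.df["depth"]):
            total = sum(
                p.points[1][1] - p.points[0][1] for p in prims if p.group == pos
            )
            assert total == depth


class TestGeomEdgeLinks:
    def _intervals(self):
        return gv.make_range_table(
            [("chr1", 100, 109), ("chr1", 500, 599), ("chr1", 2000, 2999)]
        )

    def test_slots_equal_width_in_genomic_order(self):
        prims = geom_edge_links(self._intervals())
        slots = [p for p in prims if p.aes["class"] == "slot"]
        widths = {round(p.points[1][0] - p.points[0][0], 6) for p in slots}
        assert len(slots) == 3 and len(widths) == 1
        assert [p.group for p in slots] == [0, 1, 2]

    def test_connectors_end_at_genomic_coordinates(self):
        t = self._intervals()
        prims = geom_edge_links(t)
        links = [p for p in prims if p.aes["class"] == "edge-link"]
        bottoms = sorted(p.points[1][0] for p in links)
        expected = sorted(
            list(map(float, t.starts)) + list(map(float, t.ends))
        )
        assert bottoms == expected

    def test_value_profiles(self):
        prims = geom_edge_links(
            self._intervals(), values={"GM12878": [1, 2, 3], "K562": [3, 2, 1]}
        )
        profiles = [p for p in prims if p.aes["class"] == "profile"]
        assert {p.group for p in profiles} == {"GM12878", "K562"}


class TestGeomIdeogram:
    def _bands(self):
        return gv.make_range_table(
            [("chr1", 1, 100), ("chr1", 101, 200), ("chr1", 201, 300),
             ("chr1", 301, 400), ("chr1", 401, 500), ("chr1", 501, 600)],
            metadata={"stain": ["gneg", "gpos25", "acen", "acen", "gpos100", "gneg"]},
        )

    def test_band_and_highlight_counts(self):
        prims = geom_ideogram(
            self._bands(), target=GenomicRange("chr1", 150, 250)
        )
        assert len(prims) == 7
        assert sum(p.aes["class"] == "highlight" for p in prims) == 1
        assert sum(p.kind == "polygon" for p in prims) == 2  # the acen triangles

    def test_palette_order(self):
        prims = geom_ideogram(self._bands())
        fills = [p.aes["fill"] for p in prims]
        assert fills[0] == STAIN_COLORS["gneg"] == "#FFFFFF"
        assert fills[4] == STAIN_COLORS["gpos100"] == "#000000"

    def test_unknown_stain_rejected(self):
        bad = gv.make_range_table(
            [("chr1", 1, 10)], metadata={"stain": ["gpos33"]}
        )
        with pytest.raises(ValueError, match="stain"):
            geom_ideogram(bad)

    def test_highlight_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            geom_ideogram(self._bands(), target=GenomicRange("chr1", 550, 900))
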