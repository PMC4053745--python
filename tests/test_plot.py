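"""Plot composition, autoplot dispatch, tracks, SVG rendering, CLI."""

import re

import pytest

import genoviz as gv
from genoviz.cli import run_cli
from genoviz.plot import build_primitives, empty_plot, layer_arrowrect, layer_chevron
from genoviz.ranges import GenomicRange
from genoviz.io import read_sam


class TestCompose:
    def test_theme_null_turns_flags_off(self, transcripts):
        p = gv.autoplot(transcripts)
        q = p + gv.theme_null()
        assert (q.theme.background, q.theme.axis_labels, q.theme.legend) == (
            False, False, False,
        )
        assert p.theme.background  # original unchanged

    def test_layers_append_in_order(self, transcripts):
        p = empty_plot(transcripts) + layer_arrowrect() + layer_chevron()
        assert [l.name for l in p.layers] == ["arrowrect", "chevron"]

    def test_composition_is_pure(self, transcripts):
        base = gv.autoplot(transcripts)
        a = base + gv.theme_null()
        b = base + layer_chevron(gv.gaps_within_groups(transcripts))
        assert len(base.layers) == 1
        assert len(b.layers) == 2 and a.theme != b.theme

    def test_unknown_element_rejected(self, transcripts):
        with pytest.raises(TypeError):
            gv.autoplot(transcripts) + 42


class TestAutoplot:
    def test_grouped_ranges_dispatch_to_alignment(self, transcripts):
        p = gv.autoplot(transcripts, gv.aes(color="strand"))
        prims = build_primitives(p)
        assert sum(pr.aes.get("class") == "range" for pr in prims) == 10
        assert sum(pr.aes.get("class") == "chevron" for pr in prims) == 8

    def test_plain_ranges_dispatch_to_stepped_rects(self):
        t = gv.make_range_table([("chr1", 1, 10), ("chr1", 5, 15)])
        prims = build_primitives(gv.autoplot(t))
        ys = sorted((p.points[0][1] + p.points[1][1]) / 2 for p in prims)
        assert ys == [1.0, 2.0]

    def test_alignment_table_reads_and_coverage(self, fixture_dir):
        aln = read_sam(fixture_dir["sam"])
        reads_plot = gv.autoplot(aln)
        assert reads_plot.data.group_key == "qname"
        cov_plot = gv.autoplot(aln, plot="coverage")
        (area,) = build_primitives(cov_plot)
        assert area.aes["class"] == "coverage"

    def test_coverage_rle_dispatch(self):
        cov = gv.stat_coverage(gv.make_range_table([("chr1", 1, 10)]))
        (p,) = build_primitives(gv.autoplot(cov))
        assert p.kind == "polygon"

    def test_undispatchable_rejected(self):
        with pytest.raises(TypeError, match="dispatch"):
            gv.autoplot(3.14)

    def test_empty_table_renders_axes_only(self):
        doc = gv.render_svg_string(gv.autoplot(gv.make_range_table([])))
        assert '<g class="axes">' in doc
        assert "data-group" not in doc

    def test_equivalent_to_low_level_composition(self, transcripts):
        """The dispatcher and the explicit grammar build the same plot."""
        hi = gv.autoplot(transcripts, range_geom="arrowrect")
        low = (
            empty_plot(transcripts)
            + layer_arrowrect()
            + layer_chevron(gv.gaps_within_groups(transcripts))
        )
        assert build_primitives(hi) == build_primitives(low)


class TestTracks:
    def _stack(self, transcripts):
        cov = gv.stat_coverage(transcripts)
        p1 = gv.autoplot(transcripts)
        p2 = gv.autoplot(cov)
        return gv.tracks([p1, p2], heights=[4, 1])

    def test_heights_validated(self, transcripts):
        p = gv.autoplot(transcripts)
        with pytest.raises(ValueError):
            gv.tracks([p, p], heights=[1])
        with pytest.raises(ValueError):
            gv.tracks([p], heights=[0])

    def test_shared_x_domain_is_union(self, transcripts):
        stack = self._stack(transcripts)
        lo, hi = stack.shared_x_domain()
        assert lo <= 48242968 and hi >= 48270307

    def test_stacking_preserves_member_primitives(self, transcripts):
        p1 = gv.autoplot(transcripts)
        before = build_primitives(p1)
        gv.tracks([p1, gv.autoplot(transcripts)], heights=[4, 1])
        assert build_primitives(p1) == before

    def test_zoom_and_shift(self, transcripts):
        stack = self._stack(transcripts)
        z = gv.zoom_shift(stack, window=GenomicRange("chrX", 48243000, 48245000))
        assert z.xlim == (48243000, 48245000)
        assert stack.xlim is None  # original untouched
        back = gv.zoom_shift(gv.zoom_shift(z, shift=1000), shift=-1000)
        assert back.xlim == z.xlim
        halved = gv.zoom_shift(z, factor=2.0)
        assert halved.xlim[1] - halved.xlim[0] == pytest.approx(1000.0)

    def test_zoom_wrong_seqname_rejected(self, transcripts):
        stack = self._stack(transcripts)
        with pytest.raises(ValueError, match="chr9"):
            gv.zoom_shift(stack, window=GenomicRange("chr9", 1, 10))

    def test_track_heights_in_ratio(self, transcripts):
        doc = gv.render_svg_string(self._stack(transcripts), page=(400, 500))
        # two background rects, heights in 4:1 ratio
        heights = [
            float(m) for m in re.findall(
                r'height="([\d.]+)" fill="#F7F7F7" class="background"', doc
            )
        ]
        assert len(heights) == 2
        assert heights[0] / heights[1] == pytest.approx(4.0, rel=1e-3)


class TestRenderSvg:
    def test_gene_model_svg_element_counts(self, transcripts):
        doc = gv.render_svg_string(gv.autoplot(transcripts, gv.aes(color="strand")))
        rects = re.findall(r'<rect[^>]*class="range" data-group="(\d+)"', doc)
        chevs = re.findall(r'<polyline[^>]*class="chevron" data-group="(\d+)"', doc)
        assert len(rects) == 10 and len(chevs) == 8
        assert set(rects) == set(chevs) == {"35775", "35778"}

    def test_byte_determinism(self, transcripts, tmp_path):
        plot = gv.autoplot(transcripts, gv.aes(color="strand"))
        a = gv.render_svg(plot, tmp_path / "a.svg")
        b = gv.render_svg(plot, tmp_path / "b.svg")
        assert (tmp_path / "a.svg").read_bytes() == (tmp_path / "b.svg").read_bytes()
        assert a == b

    def test_theme_null_removes_decoration(self, transcripts):
        doc = gv.render_svg_string(gv.autoplot(transcripts) + gv.theme_null())
        assert 'class="background"' not in doc
        assert 'class="tick"' not in doc
        assert 'class="legend"' not in doc

    def test_truncate_coord_applies_to_x(self, transcripts):
        sub = transcripts.subset(transcripts.df["tx_id"].to_numpy() == "35775")
        tmap = gv.build_truncate_map(gv.reduce_ranges(sub), gap_width=10)
        plot = gv.autoplot(sub) + gv.coord_truncate_gaps(tmap)
        doc = gv.render_svg_string(plot)
        assert "<svg" in doc and 'class="range"' in doc

    def test_karyogram_and_circular_and_manhattan_render(self, fixture_dir):
        import pandas as pd

        si = gv.SeqInfo((("chr1", 60000), ("chr2", 60000)))
        kdoc = gv.render_svg_string(gv.karyogram_plot(si, ncol=2))
        assert kdoc.count('class="chromosome"') == 2
        links = gv.read_table(fixture_dir["links"], "links")
        cdoc = gv.render_svg_string(gv.circular_plot(si, links=links))
        assert cdoc.count('class="arc"') == 2
        assert cdoc.count("<path") == len(links)
        scores = gv.read_table(fixture_dir["scores"], "scores")
        mdoc = gv.render_svg_string(gv.manhattan_plot(scores, si, k=5))
        assert mdoc.count('class="panel-title"') == 3  # one facet per method


class TestCli:
    def test_gene_model_subcommand(self, fixture_dir, tmp_path):
        out = tmp_path / "f.svg"
        code = run_cli([
            "gene-model", "--gff", str(fixture_dir["gff3"]),
            "--gene", "tx_id=tx1", "--coord", "truncate-gaps",
            "--gap-width", "10", "--out", str(out),
        ])
        assert code == 0 and out.exists()

    def test_simulate_deterministic(self, tmp_path):
        d1, d2 = tmp_path / "d1", tmp_path / "d2"
        assert run_cli(["simulate", "--seed", "1", "--outdir", str(d1)]) == 0
        assert run_cli(["simulate", "--seed", "1", "--outdir", str(d2)]) == 0
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_unknown_flag_exits_2(self, capsys):
        assert run_cli(["gene-model", "--bogus"]) == 2

    def test_data_error_exits_1(self, tmp_path):
        bad = tmp_path / "bad.gff3"
        bad.write_text("chr1\tx\texon\tten\t20\t.\t+\t.\tParent=t\n")
        code = run_cli([
            "gene-model", "--gff", str(bad), "--out", str(tmp_path / "o.svg"),
        ])
        assert code == 1

    def test_mismatch_and_splice_subcommands(self, fixture_dir, tmp_path):
        out = tmp_path / "mm.svg"
        code = run_cli([
            "mismatch", "--sam", str(fixture_dir["sam"]),
            "--fasta", str(fixture_dir["fasta"]),
            "--region", "chr1:200-1200", "--out", str(out),
        ])
        assert code == 0 and out.exists()
        out2 = tmp_path / "ss.svg"
        code = run_cli([
            "splice-summary", "--sam", str(fixture_dir["sam"]),
            "--gff", str(fixture_dir["gff3"]), "--coord", "truncate-gaps",
            "--out", str(out2),
        ])
        assert code == 0 and out2.exists()
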