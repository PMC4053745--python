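"""Statistical transforms: stepping, coverage, windows, mismatch pileup."""

import numpy as np
import pytest

import genoviz as gv
from genoviz.io import AlignmentTable, ReadAlignment, cigar_reference_blocks
from genoviz.ranges import GenomicRange
from genoviz.stats import stat_junctions

from conftest import brute_force_coverage


def random_tables(seed, n_sets, max_units=50, span=1000):
    rng = np.random.default_rng(seed)
    for _ in range(n_sets):
        n = int(rng.integers(1, max_units + 1))
        starts = rng.integers(1, span, n)
        widths = rng.integers(0, span // 4, n)
        yield gv.make_range_table(
            [("chr1", int(s), int(s + w)) for s, w in zip(starts, widths)]
        )


class TestStepping:
    def test_first_fit_example(self):
        t = gv.make_range_table(
            [("chr1", 1, 10), ("chr1", 5, 15), ("chr1", 12, 20)]
        )
        assert gv.stat_stepping(t) == {0: 1, 1: 2, 2: 1}

    def test_disjoint_units_all_level_one(self):
        t = gv.make_range_table([("chr1", 1, 5), ("chr1", 10, 15), ("chr1", 20, 25)])
        assert set(gv.stat_stepping(t).values()) == {1}

    def test_min_gap_forces_separation(self):
        t = gv.make_range_table([("chr1", 1, 10), ("chr1", 12, 20)])
        assert set(gv.stat_stepping(t, min_gap=0).values()) == {1}
        assert gv.stat_stepping(t, min_gap=5) == {0: 1, 1: 2}

    def test_level_count_equals_max_depth_oracle(self):
        """Greedy first-fit is level-optimal: levels == interval-graph clique
        number == max per-base coverage depth."""
        for t in random_tables(seed=7, n_sets=60, max_units=20):
            levels = gv.stat_stepping(t)
            lo, hi = int(t.starts.min()), int(t.ends.max())
            depth = brute_force_coverage(list(zip(t.starts, t.ends)), lo, hi)
            assert max(levels.values()) == max(depth)

    def test_no_same_level_overlap_with_min_gap(self):
        rng = np.random.default_rng(3)
        for t in random_tables(seed=13, n_sets=30, max_units=30):
            min_gap = int(rng.integers(0, 20))
            levels = gv.stat_stepping(t, min_gap=min_gap)
            by_level = {}
            for i, lvl in levels.items():
                by_level.setdefault(lvl, []).append(
                    (int(t.starts[i]), int(t.ends[i]))
                )
            for units in by_level.values():
                units.sort()
                for (s1, e1), (s2, e2) in zip(units, units[1:]):
                    assert s2 >= e1 + min_gap + 1

    def test_group_hull_stepping(self, transcripts):
        levels = gv.stat_stepping(transcripts, group_key="tx_id")
        assert set(levels) == {"35775", "35778"}
        # disjoint hulls pack onto the same level
        assert levels == {"35775": 1, "35778": 1}


class TestCoverage:
    def test_worked_example(self):
        t = gv.make_range_table([("chr1", 1, 5), ("chr1", 3, 7)])
        cov = gv.stat_coverage(t, window=GenomicRange("chr1", 1, 7))
        assert cov.runs == ((1, 2, 1), (3, 5, 2), (6, 7, 1))

    def test_empty_table_is_zero_run(self):
        t = gv.make_range_table([])
        cov = gv.stat_coverage(t, window=GenomicRange("chr1", 1, 10))
        assert cov.runs == ((1, 10, 0),)

    def test_conservation_identity(self):
        for t in random_tables(seed=21, n_sets=20):
            cov = gv.stat_coverage(t)
            assert cov.total == int(t.widths.sum())

    def test_rle_equals_brute_force(self):
        for t in random_tables(seed=42, n_sets=25, span=5000):
            cov = gv.stat_coverage(t)
            lo, hi = cov.domain
            assert cov.to_array().tolist() == brute_force_coverage(
                list(zip(t.starts, t.ends)), lo, hi
            )

    def test_window_pads_and_clips(self):
        t = gv.make_range_table([("chr1", 5, 8)])
        cov = gv.stat_coverage(t, window=GenomicRange("chr1", 1, 20))
        assert cov.runs == ((1, 4, 0), (5, 8, 1), (9, 20, 0))

    def test_window_seqname_mismatch_rejected(self):
        t = gv.make_range_table([("chr1", 1, 5)])
        with pytest.raises(ValueError, match="window"):
            gv.stat_coverage(t, window=GenomicRange("chr2", 1, 10))


class TestAggregate:
    def _table(self, values, start=1):
        return gv.make_range_table(
            [("chr1", start + 10 * i, start + 10 * i) for i in range(len(values))],
            metadata={"value": values},
        )

    def test_mean_windows(self):
        ws = gv.stat_aggregate(self._table([1, 2, 3, 4]), "value", k=2)
        assert [w.value for w in ws] == [1.5, 2.5, 3.5]

    def test_k1_is_identity(self):
        ws = gv.stat_aggregate(self._table([5, 7, 9]), "value", k=1)
        assert [w.value for w in ws] == [5, 7, 9]

    def test_short_seqname_yields_no_windows(self):
        assert gv.stat_aggregate(self._table([1, 2]), "value", k=5) == []

    @pytest.mark.parametrize("stat", ["mean", "sum", "max"])
    def test_matches_direct_slice_oracle(self, stat):
        rng = np.random.default_rng(9)
        values = rng.normal(size=30).round(3).tolist()
        k, step = 5, 2
        ws = gv.stat_aggregate(self._table(values), "value", k=k, stat=stat, step=step)
        agg = {"mean": np.mean, "sum": np.sum, "max": np.max}[stat]
        expected = [
            float(agg(values[i : i + k]))
            for i in range(0, len(values) - k + 1, step)
        ]
        assert [w.value for w in ws] == pytest.approx(expected)

    def test_window_hull_and_ordering(self):
        t = gv.make_range_table(
            [("chr2", 50, 60), ("chr1", 1, 5), ("chr1", 30, 42)],
            metadata={"value": [9.0, 1.0, 2.0]},
        )
        ws = gv.stat_aggregate(t, "value", k=2, stat="sum")
        assert len(ws) == 1  # only chr1 has 2 rows
        assert (ws[0].seqname, ws[0].start, ws[0].end, ws[0].value) == (
            "chr1", 1, 42, 3.0,
        )


def _read(pos, cigar, seq, seqname="chrT", qname="r1"):
    return ReadAlignment(
        qname=qname, flag=0, seqname=seqname, pos=pos, cigar=cigar, seq=seq,
        blocks=tuple(cigar_reference_blocks(pos, cigar)),
    )


class TestMismatch:
    def test_hand_pileup(self):
        ref = "ACGTACGT"
        aln = AlignmentTable([_read(1, "8M", "ACGAACGT")])
        mm = gv.stat_mismatch(aln, {"chrT": ref}, GenomicRange("chrT", 1, 8))
        row4 = mm.df[mm.df.pos == 4].iloc[0]
        assert row4["depth"] == 1 and row4["A"] == 1 and row4["match_count"] == 0
        others = mm.df[mm.df.pos != 4]
        assert (others["match_count"] == 1).all()
        assert (others[list("ACGTN")].to_numpy() == 0).all()

    def test_no_reads_all_zero(self):
        mm = gv.stat_mismatch(
            AlignmentTable([]), {"chrT": "ACGT"}, GenomicRange("chrT", 1, 4)
        )
        assert (mm.df["depth"] == 0).all()

    def test_deletion_and_skip_add_no_depth(self):
        ref = "AAAAAAAAAA"
        aln = AlignmentTable([_read(1, "3M2D3M", "AAAAAA")])
        mm = gv.stat_mismatch(aln, {"chrT": ref}, GenomicRange("chrT", 1, 10))
        assert mm.df["depth"].tolist() == [1, 1, 1, 0, 0, 1, 1, 1, 0, 0]

    def test_ambiguity_codes_tally_as_N_never_match(self):
        aln = AlignmentTable([_read(1, "4M", "ANRT")])
        mm = gv.stat_mismatch(aln, {"chrT": "ANRT"}, GenomicRange("chrT", 1, 4))
        assert mm.df["match_count"].tolist() == [1, 0, 0, 1]
        assert mm.df["N"].tolist() == [0, 1, 1, 0]

    def test_totals_conserve_depth(self):
        rng = np.random.default_rng(17)
        ref = "".join(rng.choice(list("ACGT"), 200))
        reads = []
        for i in range(40):
            pos = int(rng.integers(1, 140))
            seq = "".join(rng.choice(list("ACGT"), 30))
            reads.append(_read(pos, "10M5N10M2I8M", seq, qname=f"r{i}"))
        aln = AlignmentTable(reads)
        mm = gv.stat_mismatch(aln, {"chrT": ref}, GenomicRange("chrT", 1, 200))
        df = mm.df
        totals = df["match_count"] + df[list("ACGTN")].sum(axis=1)
        assert (totals == df["depth"]).all()
        cov = gv.stat_coverage(
            aln.blocks_table(group_by_read=False),
            window=GenomicRange("chrT", 1, 200),
        )
        assert (df["depth"].to_numpy() == cov.to_array()).all()

    def test_window_outside_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            gv.stat_mismatch(
                AlignmentTable([]), {"chrT": "ACGT"}, GenomicRange("chrT", 1, 10)
            )


class TestJunctions:
    def test_spliced_reads_counted(self):
        reads = [
            _read(1, "5M100N5M", "A" * 10, qname="a"),
            _read(1, "5M100N5M", "A" * 10, qname="b"),
            _read(3, "3M100N5M", "A" * 8, qname="c"),
        ]
        jx = stat_junctions(AlignmentTable(reads))
        assert len(jx) == 1  # all three share the junction (5, 106)
        assert jx.df["count"].tolist() == [3]
        assert (jx.starts[0], jx.ends[0]) == (5, 106)
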