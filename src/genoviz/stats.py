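"""Biological statistical transformations.

These take a :class:`~genoviz.ranges.RangeTable` (or read alignments) and
produce the quantities the geoms draw:

* :func:`stat_stepping` — assign integer display levels so overlapping
  features stack instead of overplotting (the y axis of gene-model plots).
* :func:`stat_coverage` — run-length-encoded per-base depth.
* :func:`stat_aggregate` — sliding-window aggregation of a value column over
  consecutive rows (e.g. genetic variance over windows of five SNPs).
* :func:`stat_mismatch` — per-reference-position pileup of aligned read
  bases split into matches and per-nucleotide mismatches.
* :func:`stat_junctions` — splice-junction spans and multiplicities from
  spliced (N-gapped) read alignments, the input of the arch geom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .ranges import GenomicRange, RangeTable, range_hull

__all__ = [
    "CoverageRLE",
    "WindowScore",
    "MismatchTable",
    "stat_stepping",
    "stat_coverage",
    "stat_aggregate",
    "stat_mismatch",
    "stat_junctions",
]

BASES = ("A", "C", "G", "T", "N")


# ---------------------------------------------------------------------------
# stepping


def stat_stepping(
    table: RangeTable,
    group_key: str | None = None,
    min_gap: int = 0,
) -> dict[Any, int]:
    """Greedy first-fit stepping-level assignment.

    Units are group hulls when ``group_key`` is given, otherwise individual
    rows (unit id = integer row position).  Units are packed per seqname:
    sorted by (start, longer width first, input order), each unit takes the
    smallest level whose last-placed unit ends at least ``min_gap + 1`` bp
    before the unit's start.  Levels start at 1.

    With ``min_gap=0`` the number of levels used equals the maximum per-base
    overlap depth of the unit hulls (greedy first-fit is level-optimal on
    interval graphs).
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    if group_key is not None:
        hulls = range_hull(table.with_group_key(group_key), per_group=True)
        ids = list(hulls.column(group_key))
        seqs, starts, ends = hulls.seqnames, hulls.starts, hulls.ends
    else:
        ids = list(range(len(table)))
        seqs, starts, ends = table.seqnames, table.starts, table.ends

    levels: dict[Any, int] = {}
    for seq in pd.unique(seqs):
        idx = [i for i in range(len(ids)) if seqs[i] == seq]
        idx.sort(key=lambda i: (starts[i], -(ends[i] - starts[i]), i))
        last_end: list[int] = []  # last placed end per level
        for i in idx:
            s, e = int(starts[i]), int(ends[i])
            for lvl, le in enumerate(last_end):
                if le + min_gap < s:
                    last_end[lvl] = e
                    levels[ids[i]] = lvl + 1
                    break
            else:
                last_end.append(e)
                levels[ids[i]] = len(last_end)
    return levels


# ---------------------------------------------------------------------------
# coverage


@dataclass(frozen=True)
class CoverageRLE:
    """Run-length-encoded per-base depth along one chromosome.

    ``runs`` are sorted, disjoint, abutting (start,end,depth) triples that
    tile ``domain`` exactly; adjacent runs always have different depth.
    """

    seqname: str
    runs: tuple[tuple[int, int, int], ...]
    domain: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not self.runs or self.runs[0][0] != lo or self.runs[-1][1] != hi:
            raise ValueError("runs must tile the domain")
        for (s, e, d), (s2, _, d2) in zip(self.runs, self.runs[1:]):
            if s2 != e + 1:
                raise ValueError("runs must abut")
            if d2 == d:
                raise ValueError("adjacent runs must differ in depth")
        for s, e, d in self.runs:
            if s > e or d < 0:
                raise ValueError("invalid run")

    def to_array(self) -> np.ndarray:
        """Decode to a per-base depth vector over the domain."""
        lo, hi = self.domain
        out = np.zeros(hi - lo + 1, dtype=np.int64)
        for s, e, d in self.runs:
            out[s - lo : e - lo + 1] = d
        return out

    @property
    def total(self) -> int:
        """Sum of depth x width over all runs (total covered bases)."""
        return int(sum(d * (e - s + 1) for s, e, d in self.runs))

    @property
    def max_depth(self) -> int:
        return max(d for _, _, d in self.runs)


def stat_coverage(table: RangeTable, window: GenomicRange | None = None) -> CoverageRLE:
    """Per-base depth of the input intervals, run-length encoded.

    All rows must lie on one seqname (facet by seqname first).  The default
    window is the table hull; an explicit window pads with depth-0 runs to
    the window edges and clips intervals to the window.
    """
    if len(table) == 0:
        if window is None:
            raise ValueError("coverage of an empty table requires an explicit window")
        return CoverageRLE(
            window.seqname, ((window.start, window.end, 0),),
            (window.start, window.end),
        )
    seqs = pd.unique(table.seqnames)
    if len(seqs) != 1:
        raise ValueError(f"coverage requires a single seqname, got {sorted(seqs)}")
    seqname = str(seqs[0])
    if window is None:
        window = table.hull_interval()
    elif window.seqname != seqname:
        raise ValueError(
            f"window on {window.seqname!r} but data on {seqname!r}"
        )
    ws, we = window.start, window.end
    starts = np.maximum(table.starts, ws)
    ends = np.minimum(table.ends, we)
    keep = starts <= ends
    starts, ends = starts[keep], ends[keep]
    # depth changes at interval starts (+1) and one past interval ends (-1)
    points = np.unique(np.concatenate([[ws], starts, ends + 1, [we + 1]]))
    delta = np.zeros(len(points), dtype=np.int64)
    np.add.at(delta, np.searchsorted(points, starts), 1)
    np.add.at(delta, np.searchsorted(points, ends + 1), -1)
    depth = np.cumsum(delta)
    runs: list[tuple[int, int, int]] = []
    for i in range(len(points) - 1):
        s, e, d = int(points[i]), int(points[i + 1]) - 1, int(depth[i])
        if runs and runs[-1][2] == d:
            runs[-1] = (runs[-1][0], e, d)
        else:
            runs.append((s, e, d))
    return CoverageRLE(seqname, tuple(runs), (ws, we))


# ---------------------------------------------------------------------------
# sliding-window aggregation


@dataclass(frozen=True)
class WindowScore:
    """Aggregated value over a window of k consecutive rows."""

    seqname: str
    index: int
    start: int
    end: int
    value: float


_AGG = {"mean": np.mean, "sum": np.sum, "max": np.max}


def stat_aggregate(
    table: RangeTable,
    value: str,
    k: int,
    stat: str = "mean",
    step: int = 1,
) -> list[WindowScore]:
    """Aggregate a numeric column over windows of ``k`` consecutive rows.

    Rows are sorted by (seqname, start); windows advance by ``step`` rows
    within each seqname and incomplete trailing windows are dropped.  The
    window hull spans from the first row's start to the largest end among
    the window's rows.  A seqname with fewer than ``k`` rows simply yields
    no windows.
    """
    if k < 1 or step < 1:
        raise ValueError("k and step must be >= 1")
    if stat not in _AGG:
        raise ValueError(f"stat must be one of {sorted(_AGG)}, got {stat!r}")
    if value not in table.df.columns:
        raise KeyError(f"no value column {value!r}")
    agg = _AGG[stat]
    df = table.df.sort_values(["seqname", "start"], kind="stable")
    out: list[WindowScore] = []
    for seq, sub in df.groupby("seqname", sort=True):
        vals = sub[value].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = 0
        for lo in range(0, len(sub) - k + 1, step):
            window = slice(lo, lo + k)
            out.append(
                WindowScore(
                    seqname=str(seq),
                    index=idx,
                    start=int(starts[lo]),
                    end=int(ends[window].max()),
                    value=float(agg(vals[window])),
                )
            )
            idx += 1
    return out


# ---------------------------------------------------------------------------
# mismatch pileup


@dataclass(frozen=True)
class MismatchTable:
    """Per-position pileup summary over a window.

    ``df`` has one row per reference position with columns ``pos``,
    ``ref_base``, ``A``, ``C``, ``G``, ``T``, ``N``, ``match_count`` and
    ``depth``.  The letter columns count **mismatching** query bases only
    (a query base equal to the reference is counted in ``match_count``;
    any query base outside A/C/G/T is tallied under ``N`` and never counts
    as a match), so ``match_count + A + C + G + T + N == depth`` at every
    position.  Deletions and splice skips contribute nothing to depth.
    """

    seqname: str
    df: pd.DataFrame

    @property
    def positions(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def depths(self) -> np.ndarray:
        return self.df["depth"].to_numpy()


def stat_mismatch(
    alignments,
    reference: Mapping[str, str] | str,
    window: GenomicRange,
) -> MismatchTable:
    """Pileup of aligned query bases against the reference over a window.

    ``alignments`` is an :class:`~genoviz.io.AlignmentTable` (or any iterable
    of reads with ``seqname``, ``blocks`` and ``seq`` attributes); only
    M/=/X blocks contribute, so insertions, deletions and splice skips add
    no depth.  The reference must cover the window.
    """
    if isinstance(reference, str):
        ref = reference
    else:
        if window.seqname not in reference:
            raise ValueError(f"reference has no sequence for {window.seqname!r}")
        ref = reference[window.seqname]
    if window.end > len(ref):
        raise ValueError(
            f"window [{window.start},{window.end}] outside reference "
            f"(length {len(ref)})"
        )
    ws, we = window.start, window.end
    L = we - ws + 1
    ref_arr = np.frombuffer(ref.upper().encode("ascii"), dtype="S1")[ws - 1 : we]
    counts = {b: np.zeros(L, dtype=np.int64) for b in BASES}
    match = np.zeros(L, dtype=np.int64)
    depth = np.zeros(L, dtype=np.int64)
    acgt = {b"A", b"C", b"G", b"T"}
    for read in alignments:
        if read.seqname != window.seqname:
            continue
        for bs, be, qoff in read.blocks:
            if be > len(ref):
                raise ValueError(
                    f"alignment block [{bs},{be}] beyond reference end {len(ref)}"
                )
            s, e = max(bs, ws), min(be, we)
            if s > e:
                continue
            qseg = read.seq[qoff + (s - bs) : qoff + (e - bs) + 1].upper()
            q = np.frombuffer(qseg.encode("ascii"), dtype="S1")
            lo = s - ws
            seg_ref = ref_arr[lo : lo + len(q)]
            is_acgt = np.isin(q, list(acgt))
            is_match = (q == seg_ref) & is_acgt
            depth[lo : lo + len(q)] += 1
            match[lo : lo + len(q)] += is_match
            mism = ~is_match
            for b in ("A", "C", "G", "T"):
                counts[b][lo : lo + len(q)] += mism & (q == b.encode())
            counts["N"][lo : lo + len(q)] += mism & ~is_acgt
    df = pd.DataFrame(
        {
            "pos": np.arange(ws, we + 1, dtype=np.int64),
            "ref_base": ref_arr.astype("U1"),
            **{b: counts[b] for b in BASES},
            "match_count": match,
            "depth": depth,
        }
    )
    return MismatchTable(window.seqname, df)


# ---------------------------------------------------------------------------
# splice junctions


def stat_junctions(alignments, seqname: str | None = None) -> RangeTable:
    """Splice-junction spans with multiplicities from spliced alignments.

    Each gap between consecutive reference blocks of a read (an N skip in
    the CIGAR) defines a junction from the end of the left block to the
    start of the right block.  Junctions are counted over all reads and
    returned as a RangeTable with a ``count`` column, sorted by
    (seqname, start, end).
    """
    tally: dict[tuple[str, int, int], int] = {}
    for read in alignments:
        if seqname is not None and read.seqname != seqname:
            continue
        blocks = read.blocks
        for (s1, e1, _), (s2, _, _) in zip(blocks, blocks[1:]):
            if s2 > e1 + 1:  # true skip; adjacent blocks from I ops abut
                key = (read.seqname, e1, s2)
                tally[key] = tally.get(key, 0) + 1
    keys = sorted(tally)
    df = pd.DataFrame(
        {
            "seqname": [k[0] for k in keys],
            "start": [k[1] for k in keys],
            "end": [k[2] for k in keys],
            "strand": ["*"] * len(keys),
            "count": [tally[k] for k in keys],
        }
    )
    if len(df) == 0:
        df = pd.DataFrame(
            {"seqname": [], "start": [], "end": [], "strand": [], "count": []}
        )
    return RangeTable(df, copy=False)
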