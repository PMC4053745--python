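"""Biological geoms: data → renderer-independent drawing primitives.

Each geom maps a RangeTable (or a stat output) to a list of
:class:`Primitive` objects in **data space** — x in base pairs (or
transformed plot units), y in stepping-level or value units.  Coordinate
transforms and page scaling are applied afterwards by the plot layer,
reproducing the grammar's stat → geom → coord pipeline.  Every primitive
carries the row or group id that produced it, which the SVG renderer
exposes as a ``data-group`` attribute so outputs are machine-checkable.

Geoms provided: rect / arrow-rect (exons, features), chevron (introns),
alignment (connected exon+intron glyphs per transcript), arch (splice
junctions, apex height proportional to span), coverage area, stacked
mismatch bars, edge-links (equal-width categorical interval axis joined to
true genomic positions) and ideogram (Giemsa-stained cytobands).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .ranges import GenomicRange, RangeTable, gaps_within_groups
from .stats import BASES, CoverageRLE, MismatchTable, stat_stepping

__all__ = [
    "Primitive",
    "Aes",
    "aes",
    "PALETTE",
    "STRAND_COLORS",
    "BASE_COLORS",
    "STAIN_COLORS",
    "MATCH_COLOR",
    "geom_rect",
    "geom_chevron",
    "geom_alignment",
    "geom_arch",
    "geom_coverage_area",
    "geom_mismatch_bars",
    "geom_edge_links",
    "geom_ideogram",
]

# Fixed, documented colorblind-safe palette (Okabe-Ito) for categorical
# aesthetics; strand and nucleotide colors are fixed lookups.
PALETTE = (
    "#0072B2", "#D55E00", "#009E73", "#CC79A7",
    "#E69F00", "#56B4E9", "#F0E442", "#000000",
)
STRAND_COLORS = {"+": "#0072B2", "-": "#D55E00", "*": "#7F7F7F"}
BASE_COLORS = {
    "A": "#009E73", "C": "#0072B2", "G": "#E69F00", "T": "#D55E00",
    "N": "#999999",
}
MATCH_COLOR = "#BDBDBD"  # neutral gray for reference-matching bases

# Giemsa stain vocabulary → gray levels, light (gneg) to dark (gpos100);
# acen is the centromere red used by convention.
STAIN_COLORS = {
    "gneg": "#FFFFFF",
    "gpos25": "#C8C8C8",
    "gpos50": "#969696",
    "gpos75": "#646464",
    "gpos100": "#000000",
    "gvar": "#DCDCDC",
    "stalk": "#647FA4",
    "acen": "#D92F27",
}
HIGHLIGHT_COLOR = "#E41A1C"


@dataclass
class Primitive:
    """One renderer-independent drawing primitive.

    kinds: ``rect`` (two corner points), ``polyline``, ``polygon``,
    ``bezier`` (p0, control, p1 of a quadratic curve), ``point`` (one
    point), ``text`` (one anchor point, string in ``aes['text']``).
    """

    kind: str
    points: tuple[tuple[float, float], ...]
    aes: dict[str, Any] = field(default_factory=dict)
    group: Any = None

    def __post_init__(self) -> None:
        for x, y in self.points:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinate in {self.kind} primitive")
        if self.kind == "rect":
            (x1, y1), (x2, y2) = self.points
            if x1 > x2 or y1 > y2:
                raise ValueError("rect requires x1 <= x2 and y1 <= y2")

    @property
    def x_extent(self) -> tuple[float, float]:
        xs = [p[0] for p in self.points]
        return min(xs), max(xs)


@dataclass(frozen=True)
class Aes:
    """Aesthetic mapping: aesthetic name → metadata column or constant.

    Only column *names* are stored; resolution against a concrete table
    happens inside each geom.  Unmapped aesthetics take the geom's
    documented defaults.
    """

    color: str | None = None
    fill: str | None = None
    size: str | None = None
    alpha: str | None = None


def aes(**kwargs: str) -> Aes:
    """Convenience constructor, e.g. ``aes(color="strand")``."""
    return Aes(**kwargs)


def _categorical_colors(values: Sequence[Any]) -> dict[Any, str]:
    """Deterministic value→color assignment in order of first appearance."""
    mapping: dict[Any, str] = {}
    for v in values:
        if v not in mapping:
            mapping[v] = PALETTE[len(mapping) % len(PALETTE)]
    return mapping


def _resolve_colors(
    table: RangeTable, mapping: Aes | None, default: str
) -> tuple[list[str], list[Any | None]]:
    """Per-row fill colors plus the legend label for each row (or None)."""
    n = len(table)
    col = None
    if mapping is not None:
        col = mapping.color or mapping.fill
    if col is None:
        return [default] * n, [None] * n
    if col not in table.df.columns:
        raise KeyError(f"aesthetic column {col!r} not in table")
    values = list(table.df[col])
    if col == "strand":
        lut: Mapping[Any, str] = STRAND_COLORS
    else:
        lut = _categorical_colors(values)
    return [lut.get(v, PALETTE[0]) for v in values], values


def _row_levels(table: RangeTable, y: str | float) -> np.ndarray:
    if isinstance(y, str):
        if y not in table.df.columns:
            raise KeyError(f"y column {y!r} not in table")
        return table.df[y].to_numpy(dtype=float)
    return np.full(len(table), float(y))


# ---------------------------------------------------------------------------
# rect / arrow-rect


def geom_rect(
    table: RangeTable,
    aes: Aes | None = None,
    shape: str = "plain",
    y: str | float = 0.0,
    height: float = 0.8,
    notch: float | None = None,
) -> list[Primitive]:
    """One rectangle per interval, centred on its level.

    ``shape="arrow"`` emits a strand-aware pointed polygon instead: the tip
    extends ``notch`` bp beyond the end for ``+`` strand (beyond the start,
    leftwards, for ``-``); unstranded rows fall back to plain rectangles.
    ``notch`` defaults to 2% of the table hull width.
    """
    if shape not in ("plain", "arrow"):
        raise ValueError(f"shape must be plain or arrow, got {shape!r}")
    if len(table) == 0:
        return []
    levels = _row_levels(table, y)
    fills, labels = _resolve_colors(table, aes, default=PALETTE[0])
    if notch is None:
        hull_w = float(table.ends.max() - table.starts.min())
        notch = 0.02 * max(hull_w, 1.0)
    gids = (
        list(table.df[table.group_key]) if table.group_key else list(range(len(table)))
    )
    prims: list[Primitive] = []
    h2 = height / 2.0
    for i, (s, e, st, lv) in enumerate(
        zip(table.starts, table.ends, table.strands, levels)
    ):
        a: dict[str, Any] = {"fill": fills[i], "class": "range"}
        if labels[i] is not None:
            a["legend_label"] = labels[i]
        if shape == "arrow" and st in ("+", "-"):
            if st == "+":
                pts = (
                    (float(s), lv - h2), (float(e), lv - h2),
                    (float(e) + notch, lv), (float(e), lv + h2),
                    (float(s), lv + h2),
                )
            else:
                pts = (
                    (float(e), lv - h2), (float(s), lv - h2),
                    (float(s) - notch, lv), (float(s), lv + h2),
                    (float(e), lv + h2),
                )
            prims.append(Primitive("polygon", pts, a, group=gids[i]))
        else:
            prims.append(
                Primitive(
                    "rect",
                    ((float(s), lv - h2), (float(e), lv + h2)),
                    a,
                    group=gids[i],
                )
            )
    return prims


# ---------------------------------------------------------------------------
# chevron


def geom_chevron(
    table: RangeTable,
    aes: Aes | None = None,
    y: str | float = 0.0,
    apex_offset: float = 0.25,
) -> list[Primitive]:
    """The intron glyph: a two-segment polyline rising to a midpoint apex.

    Per gap, a polyline from (start, y) up to ((start+end)/2, y+apex_offset)
    and down to (end, y).  ``apex_offset=0`` degenerates to a straight
    segment.
    """
    if len(table) == 0:
        return []
    levels = _row_levels(table, y)
    strokes, labels = _resolve_colors(table, aes, default="#555555")
    gids = (
        list(table.df[table.group_key]) if table.group_key else list(range(len(table)))
    )
    prims: list[Primitive] = []
    for i, (s, e, lv) in enumerate(zip(table.starts, table.ends, levels)):
        mid = (float(s) + float(e)) / 2.0
        a: dict[str, Any] = {"stroke": strokes[i], "class": "chevron"}
        if labels[i] is not None:
            a["legend_label"] = labels[i]
        prims.append(
            Primitive(
                "polyline",
                ((float(s), lv), (mid, lv + apex_offset), (float(e), lv)),
                a,
                group=gids[i],
            )
        )
    return prims


def _geom_gap_segment(
    table: RangeTable, aes: Aes | None, y: str | float
) -> list[Primitive]:
    """Straight connector used as the gap glyph for read alignments."""
    prims = geom_chevron(table, aes, y=y, apex_offset=0.0)
    for p in prims:
        p.aes["class"] = "gap-segment"
    return prims


# ---------------------------------------------------------------------------
# alignment (connected exon/intron glyphs)


def _alignment_levels(table: RangeTable, min_gap: int) -> dict[Any, int]:
    if table.group_key is None:
        raise ValueError("geom_alignment requires a grouped RangeTable")
    return stat_stepping(table, group_key=table.group_key, min_gap=min_gap)


def _with_levels(table: RangeTable, levels: Mapping[Any, int]) -> RangeTable:
    vals = [levels[g] for g in table.df[table.group_key]]
    return table.with_column("__level__", vals)


def geom_alignment(
    table: RangeTable,
    aes: Aes | None = None,
    range_geom: str = "rect",
    gap_geom: str = "chevron",
    height: float = 0.8,
    min_gap: int = 0,
    apex_offset: float = 0.25,
) -> list[Primitive]:
    """Connected gene-model / read glyphs per group.

    Each group (transcript, read) gets one stepping level from its hull;
    member intervals are drawn with ``range_geom`` (rect or arrowrect) and
    the gaps between them with ``gap_geom`` (chevron or segment), all on the
    group's level and carrying the group id.  Range primitives are emitted
    first (all groups), then gap primitives, matching the layer order of the
    equivalent low-level composition.
    """
    if range_geom not in ("rect", "arrowrect"):
        raise ValueError(f"range_geom must be rect or arrowrect, got {range_geom!r}")
    if gap_geom not in ("chevron", "segment"):
        raise ValueError(f"gap_geom must be chevron or segment, got {gap_geom!r}")
    levels = _alignment_levels(table, min_gap)
    ranged = _with_levels(table, levels)
    shape = "arrow" if range_geom == "arrowrect" else "plain"
    prims = geom_rect(ranged, aes, shape=shape, y="__level__", height=height)
    gaps = gaps_within_groups(table)
    if len(gaps):
        gaps = _with_levels(gaps, levels)
        if gap_geom == "chevron":
            prims += geom_chevron(gaps, aes, y="__level__", apex_offset=apex_offset)
        else:
            prims += _geom_gap_segment(gaps, aes, y="__level__")
    return prims


# ---------------------------------------------------------------------------
# arch (splice junctions)


def geom_arch(
    junctions: RangeTable,
    aes: Aes | None = None,
    height_scale: float = 0.3,
    base: float = 0.0,
    count: str = "count",
    size_floor: float = 0.5,
) -> list[Primitive]:
    """One arch per junction; apex height proportional to span.

    Quadratic Bezier from (start, base) to (end, base) whose apex sits at
    ``height_scale * (end - start)`` above the base (the control point is at
    twice that, since the curve reaches half the control height).  Stroke
    size encodes the junction count on a square-root scale with a floor of
    ``size_floor`` so zero-count junctions are still drawn.
    """
    if len(junctions) == 0:
        return []
    if count in junctions.df.columns:
        counts = junctions.df[count].to_numpy(dtype=float)
        if (counts < 0).any():
            raise ValueError("junction counts must be >= 0")
    else:
        counts = np.ones(len(junctions))
    strokes, labels = _resolve_colors(junctions, aes, default=PALETTE[0])
    prims: list[Primitive] = []
    for i, (s, e) in enumerate(zip(junctions.starts, junctions.ends)):
        span = float(e) - float(s)
        apex = height_scale * span
        mid = (float(s) + float(e)) / 2.0
        a: dict[str, Any] = {
            "stroke": strokes[i],
            "size": max(size_floor, math.sqrt(counts[i])),
            "class": "arch",
        }
        if labels[i] is not None:
            a["legend_label"] = labels[i]
        prims.append(
            Primitive(
                "bezier",
                ((float(s), base), (mid, base + 2.0 * apex), (float(e), base)),
                a,
                group=i,
            )
        )
    return prims


# ---------------------------------------------------------------------------
# coverage area


def geom_coverage_area(cov: CoverageRLE, aes: Aes | None = None) -> list[Primitive]:
    """A single step polygon tracing the run depths, closed to the baseline.

    Run edges sit at start-0.5 and end+0.5 so the polygon area equals
    sum(depth x width) — the total number of covered bases.  Vertex x
    coordinates are non-decreasing.
    """
    lo, hi = cov.domain
    pts: list[tuple[float, float]] = [(lo - 0.5, 0.0)]
    for s, e, d in cov.runs:
        pts.append((s - 0.5, float(d)))
        pts.append((e + 0.5, float(d)))
    pts.append((hi + 0.5, 0.0))
    fill = "#4C72B0"
    return [
        Primitive(
            "polygon", tuple(pts), {"fill": fill, "class": "coverage"},
            group=cov.seqname,
        )
    ]


# ---------------------------------------------------------------------------
# mismatch bars


def geom_mismatch_bars(mm: MismatchTable, aes: Aes | None = None) -> list[Primitive]:
    """Stacked per-position bars: gray matches, then mismatches by base.

    Segments stack in the fixed order match, A, C, G, T, N; zero-height
    segments are omitted; segment heights at a position always sum to its
    depth.  Bars are one base wide (pos +- 0.5).
    """
    prims: list[Primitive] = []
    df = mm.df
    for row in df.itertuples(index=False):
        x0, x1 = row.pos - 0.5, row.pos + 0.5
        y = 0.0
        segments = [("match", row.match_count, MATCH_COLOR)]
        segments += [(b, getattr(row, b), BASE_COLORS[b]) for b in BASES]
        for name, h, color in segments:
            if h <= 0:
                continue
            prims.append(
                Primitive(
                    "rect",
                    ((float(x0), y), (float(x1), y + float(h))),
                    {"fill": color, "class": f"mismatch-{name}"},
                    group=int(row.pos),
                )
            )
            y += float(h)
    return prims


# ---------------------------------------------------------------------------
# edge links (equal-width interval axis joined to genomic positions)


def geom_edge_links(
    intervals: RangeTable,
    values: Mapping[str, Sequence[float]] | None = None,
) -> list[Primitive]:
    """Equal-width interval slots linked to their true genomic extents.

    Interval i (in genomic start order, one seqname) occupies slot i of an
    equal-width categorical band laid over the data hull: slot width =
    hull_width / n regardless of interval size.  Connector segments join
    each slot's left and right edges (slot band bottom, y=1) to the
    interval's genomic start and end on the position axis (y=0).  Optional
    per-sample value profiles are drawn as polylines through the slot
    centres above the band (y = 2 + value rescaled to [0,1]).
    """
    n = len(intervals)
    if n == 0:
        return []
    seqs = set(intervals.seqnames)
    if len(seqs) != 1:
        raise ValueError("edge links require a single seqname")
    order = np.argsort(intervals.starts, kind="stable")
    starts = intervals.starts[order]
    ends = intervals.ends[order]
    hull_lo, hull_hi = float(intervals.starts.min()), float(intervals.ends.max())
    slot_w = (hull_hi - hull_lo) / n
    prims: list[Primitive] = []
    slot_edges = []
    for i in range(n):
        x0 = hull_lo + i * slot_w
        x1 = x0 + slot_w
        slot_edges.append((x0, x1))
        prims.append(
            Primitive(
                "rect", ((x0, 1.0), (x1, 1.6)),
                {"fill": "#E8E8E8", "stroke": "#888888", "class": "slot"},
                group=i,
            )
        )
    for i in range(n):
        x0, x1 = slot_edges[i]
        prims.append(
            Primitive(
                "polyline", ((x0, 1.0), (float(starts[i]), 0.0)),
                {"stroke": "#888888", "class": "edge-link"}, group=i,
            )
        )
        prims.append(
            Primitive(
                "polyline", ((x1, 1.0), (float(ends[i]), 0.0)),
                {"stroke": "#888888", "class": "edge-link"}, group=i,
            )
        )
    if values:
        all_vals = [v for vs in values.values() for v in vs]
        vlo, vhi = min(all_vals), max(all_vals)
        vspan = (vhi - vlo) or 1.0
        colors = _categorical_colors(list(values))
        for sample, vs in values.items():
            if len(vs) != n:
                raise ValueError(
                    f"values for {sample!r} must have one entry per interval"
                )
            pts = tuple(
                ((slot_edges[i][0] + slot_edges[i][1]) / 2.0,
                 2.0 + (float(vs[i]) - vlo) / vspan)
                for i in range(n)
            )
            prims.append(
                Primitive(
                    "polyline", pts,
                    {"stroke": colors[sample], "class": "profile",
                     "legend_label": sample},
                    group=sample,
                )
            )
    return prims


# ---------------------------------------------------------------------------
# ideogram


def geom_ideogram(
    cytobands: RangeTable,
    target: GenomicRange | None = None,
    stain: str = "stain",
) -> list[Primitive]:
    """Chromosome ideogram strip from a cytoband table.

    Bands are filled from the fixed Giemsa stain palette; centromeric
    (``acen``) bands are drawn as triangles pointing inward.  An optional
    target region is overlaid as a red highlight rectangle and must fall
    within the chromosome (the cytoband hull).
    """
    if len(cytobands) == 0:
        raise ValueError("empty cytoband table")
    if stain not in cytobands.df.columns:
        raise KeyError(f"no stain column {stain!r}")
    seqs = set(cytobands.seqnames)
    if len(seqs) != 1:
        raise ValueError("ideogram requires a single seqname")
    stains = list(cytobands.df[stain])
    unknown = set(stains) - set(STAIN_COLORS)
    if unknown:
        raise ValueError(f"unknown stain value(s): {sorted(unknown)}")
    prims: list[Primitive] = []
    hull_lo = int(cytobands.starts.min())
    hull_hi = int(cytobands.ends.max())
    mid = (hull_lo + hull_hi) / 2.0
    for i, (s, e, st) in enumerate(zip(cytobands.starts, cytobands.ends, stains)):
        color = STAIN_COLORS[st]
        if st == "acen":
            # triangle apex points toward the chromosome centre
            apex_x = float(e) if (s + e) / 2.0 <= mid else float(s)
            base_x = float(s) if apex_x == float(e) else float(e)
            pts = ((base_x, 0.0), (base_x, 1.0), (apex_x, 0.5))
            prims.append(
                Primitive("polygon", pts, {"fill": color, "class": "band"}, group=i)
            )
        else:
            prims.append(
                Primitive(
                    "rect", ((float(s), 0.0), (float(e), 1.0)),
                    {"fill": color, "stroke": "#000000", "class": "band"},
                    group=i,
                )
            )
    if target is not None:
        if target.seqname != seqs.pop():
            raise ValueError("highlight on a different seqname")
        if target.start < hull_lo or target.end > hull_hi:
            raise ValueError(
                f"highlight [{target.start},{target.end}] outside chromosome "
                f"[{hull_lo},{hull_hi}]"
            )
        prims.append(
            Primitive(
                "rect",
                ((float(target.start), -0.15), (float(target.end), 1.15)),
                {"fill": "none", "stroke": HIGHLIGHT_COLOR, "size": 1.5,
                 "class": "highlight"},
                group="highlight",
            )
        )
    return prims
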