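"""Layout engines: arrange genomic coordinates on the page.

Three layouts are supported, mirroring the layout component of the extended
grammar: *linear* (one panel per chromosome sharing the page), *karyogram*
(chromosomes as an array of scaled rectangles) and *circular* (the genome
wrapped around a circle, data in concentric rings, relationships drawn as
curved links).  :func:`facet_by_ranges` additionally facets a plot by an
arbitrary list of labelled regions of interest.

Page extents use a unit page: x and y in [0, ncols] x [0, nrows] grid
coordinates; the renderer scales these onto the SVG canvas.

Circular convention: angles are compass degrees (0 at 12 o'clock), the
default direction is clockwise, and chromosome arcs are separated by a 5
degree gap by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import pandas as pd

from .coords import GenomeCoordMap, genome_to_global
from .ranges import GenomicRange, RangeTable, SeqInfo

__all__ = [
    "PanelPlacement",
    "RingSpec",
    "LinkPath",
    "layout_linear",
    "layout_karyogram",
    "make_ring",
    "circular_position",
    "link_path",
    "facet_by_ranges",
]


@dataclass(frozen=True)
class PanelPlacement:
    """One panel of a multi-panel layout."""

    panel: str
    row: int  # 1-based grid row
    col: int  # 1-based grid column
    x_domain: tuple[float, float]  # in data units
    extent: tuple[float, float, float, float]  # page units: x0, y0, width, height


# ---------------------------------------------------------------------------
# linear


def layout_linear(
    tables: Sequence[RangeTable] | RangeTable,
    window: GenomicRange | None = None,
    seqinfo: SeqInfo | None = None,
) -> list[PanelPlacement]:
    """One panel per seqname present in the data (implicit chromosome facet).

    Panels stack vertically in SeqInfo order when a SeqInfo is available
    (from the argument or the first table), else in order of first
    appearance.  An explicit window restricts the layout to a single panel
    whose x-domain is the window, not the data hull.
    """
    if isinstance(tables, RangeTable):
        tables = [tables]
    if seqinfo is None:
        for t in tables:
            if t.seqinfo is not None:
                seqinfo = t.seqinfo
                break
    present: list[str] = []
    hulls: dict[str, tuple[float, float]] = {}
    for t in tables:
        for seq, sub in t.df.groupby("seqname", sort=False):
            seq = str(seq)
            lo, hi = int(sub["start"].min()), int(sub["end"].max())
            if seq in hulls:
                hulls[seq] = (min(hulls[seq][0], lo), max(hulls[seq][1], hi))
            else:
                present.append(seq)
                hulls[seq] = (lo, hi)
    if window is not None:
        if window.seqname not in hulls and (
            seqinfo is None or window.seqname not in seqinfo
        ):
            raise ValueError(
                f"window seqname {window.seqname!r} absent from data and SeqInfo"
            )
        panels = [window.seqname]
        hulls[window.seqname] = (window.start, window.end)
    else:
        if seqinfo is not None:
            known = [s for s in seqinfo.names if s in hulls]
            panels = known + [s for s in present if s not in set(known)]
        else:
            panels = present
    n = max(len(panels), 1)
    return [
        PanelPlacement(
            panel=seq, row=i + 1, col=1, x_domain=hulls[seq],
            extent=(0.0, float(i), 1.0, 1.0),
        )
        for i, seq in enumerate(panels)
    ]


# ---------------------------------------------------------------------------
# karyogram


def layout_karyogram(seqinfo: SeqInfo, ncol: int = 1) -> list[PanelPlacement]:
    """Chromosome array: row-major grid in SeqInfo order.

    Each panel's x-domain is [1, chromosome length] and its page width is
    proportional to the chromosome's length relative to the longest, so the
    panels read as a scaled karyotype.
    """
    if len(seqinfo) == 0:
        raise ValueError("empty SeqInfo")
    if ncol < 1:
        raise ValueError("ncol must be >= 1")
    max_len = max(l for _, l in seqinfo.entries)
    placements = []
    for i, (seqname, length) in enumerate(seqinfo.entries):
        row, col = divmod(i, ncol)
        width = length / max_len
        placements.append(
            PanelPlacement(
                panel=seqname, row=row + 1, col=col + 1,
                x_domain=(1.0, float(length)),
                extent=(float(col), float(row), width, 1.0),
            )
        )
    return placements


# ---------------------------------------------------------------------------
# circular


@dataclass(frozen=True)
class RingSpec:
    """A concentric ring of a circular layout.

    ``spans`` maps each seqname to its (arc_start, arc_span) in degrees
    measured from ``start_angle`` along ``direction``; consecutive arcs are
    separated by exactly ``gap_degrees`` and, on a full circle, a closing
    gap follows the last chromosome so the spans plus gaps sum to
    ``total_degrees``.
    """

    ring_index: int
    inner_radius: float
    outer_radius: float
    start_angle: float = 0.0
    direction: int = 1  # 1 = clockwise in compass convention, -1 = ccw
    total_degrees: float = 360.0
    gap_degrees: float = 5.0
    spans: tuple[tuple[str, float, float], ...] = ()  # (seqname, arc_start, arc_span)

    def arc(self, seqname: str) -> tuple[float, float]:
        for name, a0, span in self.spans:
            if name == seqname:
                return a0, span
        raise KeyError(f"no arc for seqname {seqname!r}")


def make_ring(
    coord_map: GenomeCoordMap,
    ring_index: int,
    inner_radius: float,
    outer_radius: float,
    start_angle: float = 0.0,
    direction: int = 1,
    total_degrees: float = 360.0,
    gap_degrees: float = 5.0,
) -> RingSpec:
    """Compute per-chromosome arc spans for one ring.

    Arc spans are proportional to the chromosome image widths of the genome
    map (so a uniform map yields equal arcs, a proportional map arcs
    proportional to length).  On a full circle every chromosome is followed
    by a gap (including the last, closing the circle); otherwise only the
    n-1 internal gaps are inserted.
    """
    if inner_radius < 0 or outer_radius <= inner_radius:
        raise ValueError("require 0 <= inner_radius < outer_radius")
    if direction not in (1, -1):
        raise ValueError("direction must be 1 (clockwise) or -1")
    names = coord_map.seqinfo.names
    widths = [
        length * scale
        for (_, length), scale in zip(coord_map.seqinfo.entries, coord_map.scales)
    ]
    n_gaps = len(names) if math.isclose(total_degrees, 360.0) else len(names) - 1
    avail = total_degrees - n_gaps * gap_degrees
    if avail <= 0:
        raise ValueError("gaps consume the whole angular domain")
    total_w = sum(widths)
    spans = []
    cursor = 0.0
    for name, w in zip(names, widths):
        span = avail * w / total_w
        spans.append((name, cursor, span))
        cursor += span + gap_degrees
    return RingSpec(
        ring_index=ring_index, inner_radius=inner_radius,
        outer_radius=outer_radius, start_angle=start_angle,
        direction=direction, total_degrees=total_degrees,
        gap_degrees=gap_degrees, spans=tuple(spans),
    )


def circular_position(
    ring: RingSpec,
    coord_map: GenomeCoordMap,
    locus: tuple[str, float],
    radius_fraction: float = 0.0,
) -> tuple[float, float]:
    """Map a locus to (angle in degrees, radius in page units) on a ring.

    The within-chromosome fraction is pos/length, so the last base of each
    chromosome lands exactly at the end of its arc and, with no gaps, the
    map sends the full genome span onto exactly ``total_degrees``.
    ``radius_fraction`` interpolates inner → outer radius.
    """
    if not (0.0 <= radius_fraction <= 1.0):
        raise ValueError("radius_fraction must be in [0, 1]")
    seqname, pos = locus
    genome_to_global(coord_map, locus)  # validates seqname and bounds
    length = coord_map.seqinfo.length(seqname)
    arc_start, span = ring.arc(seqname)
    angle = ring.start_angle + ring.direction * (arc_start + span * pos / length)
    radius = ring.inner_radius + radius_fraction * (
        ring.outer_radius - ring.inner_radius
    )
    return angle, radius


def _angle_to_xy(angle: float, radius: float) -> tuple[float, float]:
    """Compass angle (0 deg at 12 o'clock, clockwise) to centred xy."""
    rad = math.radians(angle)
    return radius * math.sin(rad), radius * math.cos(rad)


@dataclass(frozen=True)
class LinkPath:
    """A curved link between two loci on the link ring's inner radius."""

    endpoints: tuple[tuple[float, float], tuple[float, float]]  # (angle, radius) x2
    control: tuple[float, float]  # centred page xy of the Bezier control point
    class_label: str  # intra | inter

    @property
    def xy(self) -> tuple[tuple[float, float], tuple[float, float]]:
        (a0, r0), (a1, r1) = self.endpoints
        return _angle_to_xy(a0, r0), _angle_to_xy(a1, r1)


def link_path(
    ring: RingSpec,
    coord_map: GenomeCoordMap,
    locus_a: tuple[str, float],
    locus_b: tuple[str, float],
    curvature: float = 0.2,
) -> LinkPath:
    """Quadratic Bezier between two loci on the ring's inner radius.

    The control point sits at ``curvature * inner_radius`` from the centre
    along the direction of the chord midpoint, so curvature 0 routes the
    path through the exact centre.  The class label is ``intra`` when both
    loci share a seqname, else ``inter``.
    """
    a = circular_position(ring, coord_map, locus_a, 0.0)
    b = circular_position(ring, coord_map, locus_b, 0.0)
    pa, pb = _angle_to_xy(*a), _angle_to_xy(*b)
    mx, my = (pa[0] + pb[0]) / 2.0, (pa[1] + pb[1]) / 2.0
    norm = math.hypot(mx, my)
    if norm < 1e-12 or curvature == 0.0:
        control = (0.0, 0.0)
    else:
        k = curvature * ring.inner_radius / norm
        control = (mx * k, my * k)
    label = "intra" if locus_a[0] == locus_b[0] else "inter"
    return LinkPath(endpoints=(a, b), control=control, class_label=label)


# ---------------------------------------------------------------------------
# facet by ranges


def facet_by_ranges(
    table: RangeTable,
    which: Sequence[tuple[str, GenomicRange]],
) -> tuple[list[PanelPlacement], dict[str, RangeTable]]:
    """One panel per labelled range of interest.

    Each panel holds the rows overlapping its range (a row straddling two
    ranges appears in both) and its x-domain is clipped to the range.
    Empty panels are allowed; duplicate labels are not.
    """
    labels = [lab for lab, _ in which]
    if len(set(labels)) != len(labels):
        raise ValueError("facet labels must be unique")
    placements: list[PanelPlacement] = []
    subsets: dict[str, RangeTable] = {}
    for i, (label, rng) in enumerate(which):
        mask = (
            (table.df["seqname"] == rng.seqname)
            & (table.df["start"] <= rng.end)
            & (table.df["end"] >= rng.start)
        )
        subsets[label] = table.subset(mask.to_numpy())
        placements.append(
            PanelPlacement(
                panel=label, row=i + 1, col=1,
                x_domain=(float(rng.start), float(rng.end)),
                extent=(0.0, float(i), 1.0, 1.0),
            )
        )
    return placements, subsets
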