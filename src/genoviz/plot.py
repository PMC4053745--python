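"""User-facing plot composition.

The central object is the immutable :class:`PlotSpec` — data, an ordered
list of layers (stat + geom + aesthetics), one coordinate transform, a
layout and a theme.  Specs compose with ``+`` (each composition returns a
*new* spec, so a saved plot can be re-themed later):

    p = autoplot(transcripts, aes(color="strand"))
    render_svg(p + theme_null(), "gene_model.svg")

:func:`autoplot` recognises the data structure and builds the appropriate
plot: a grouped RangeTable becomes a gene-model/alignment plot with
stepping levels, a plain RangeTable rectangles on stepping levels, an
AlignmentTable stepped reads or a coverage area, a CoverageRLE an area
plot.  The dispatch table is the module-level ``AUTOPLOT_REGISTRY`` and can
be extended with ``register_autoplot``.

:func:`tracks` stacks plots over one shared genomic axis with relative
heights; :func:`zoom_shift` changes the shared window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import geoms
from .coords import TruncateGapsMap, build_genome_map, genome_to_global
from .geoms import Aes, Primitive
from .io import AlignmentTable
from .layouts import (
    PanelPlacement,
    layout_karyogram,
    link_path,
    make_ring,
)
from .ranges import GenomicRange, RangeTable, SeqInfo, make_range_table
from .stats import CoverageRLE, stat_aggregate, stat_coverage, stat_stepping

__all__ = [
    "Theme",
    "theme_null",
    "Coord",
    "coord_identity",
    "coord_truncate_gaps",
    "Layer",
    "PlotSpec",
    "empty_plot",
    "compose",
    "autoplot",
    "register_autoplot",
    "AUTOPLOT_REGISTRY",
    "tracks",
    "zoom_shift",
    "TrackStack",
    "layer_rect",
    "layer_arrowrect",
    "layer_chevron",
    "layer_alignment",
    "layer_area",
    "layer_arch",
    "layer_mismatch",
    "layer_points",
    "layer_primitives",
    "build_primitives",
    "manhattan_plot",
    "karyogram_plot",
    "circular_plot",
]


# ---------------------------------------------------------------------------
# themes and coords


@dataclass(frozen=True)
class Theme:
    background: bool = True
    axis_labels: bool = True
    legend: bool = True


def theme_null() -> Theme:
    """Remove background, axis labels and legend."""
    return Theme(background=False, axis_labels=False, legend=False)


@dataclass(frozen=True)
class Coord:
    """Coordinate transform applied to primitive x coordinates at render.

    ``identity`` leaves data coordinates alone; ``truncate_gaps`` carries a
    :class:`~genoviz.coords.TruncateGapsMap` whose forward map compresses
    the gaps between kept intervals.  (Whole-genome concatenation is a
    data-level transform: multi-chromosome plots are built in global
    coordinates, see :func:`manhattan_plot`.)
    """

    kind: str = "identity"
    truncate_map: TruncateGapsMap | None = None

    def forward(self, x: float) -> float:
        if self.kind == "identity":
            return x
        m = self.truncate_map
        lo, hi = m.domain
        return float(m._forward(min(max(x, lo), hi)))


def coord_identity() -> Coord:
    return Coord()


def coord_truncate_gaps(truncate_map: TruncateGapsMap) -> Coord:
    return Coord(kind="truncate_gaps", truncate_map=truncate_map)


# ---------------------------------------------------------------------------
# layers


@dataclass(frozen=True)
class Layer:
    """One stat+geom layer; ``build`` maps data → primitives."""

    name: str
    build: Callable[[Any], list[Primitive]]
    data: Any = None


def _stepped(table: RangeTable, min_gap: int = 0) -> RangeTable:
    """Attach a ``__level__`` stepping column (by group when grouped)."""
    if table.group_key is not None:
        levels = stat_stepping(table, group_key=table.group_key, min_gap=min_gap)
        vals = [levels[g] for g in table.df[table.group_key]]
    else:
        levels = stat_stepping(table, min_gap=min_gap)
        vals = [levels[i] for i in range(len(table))]
    return table.with_column("__level__", vals)


def layer_rect(
    data: RangeTable | None = None,
    aes: Aes | None = None,
    shape: str = "plain",
    stat: str = "stepping",
    y: float | str | None = None,
    height: float = 0.8,
    min_gap: int = 0,
) -> Layer:
    """Rectangles (or arrow rects) on stepping levels (or a fixed y)."""

    def build(d: RangeTable) -> list[Primitive]:
        if stat == "stepping" and y is None:
            return geoms.geom_rect(
                _stepped(d, min_gap), aes, shape=shape, y="__level__", height=height
            )
        return geoms.geom_rect(d, aes, shape=shape, y=y or 0.0, height=height)

    return Layer(name="arrowrect" if shape == "arrow" else "rect",
                 build=build, data=data)


def layer_arrowrect(data=None, aes=None, **kw) -> Layer:
    return layer_rect(data, aes, shape="arrow", **kw)


def layer_chevron(
    data: RangeTable | None = None,
    aes: Aes | None = None,
    stat: str = "stepping",
    y: float | str | None = None,
    apex_offset: float = 0.25,
    min_gap: int = 0,
) -> Layer:
    """Chevrons over gap intervals, on stepping levels by default."""

    def build(d: RangeTable) -> list[Primitive]:
        if stat == "stepping" and y is None:
            return geoms.geom_chevron(
                _stepped(d, min_gap), aes, y="__level__", apex_offset=apex_offset
            )
        return geoms.geom_chevron(d, aes, y=y or 0.0, apex_offset=apex_offset)

    return Layer(name="chevron", build=build, data=data)


def layer_alignment(
    data: RangeTable | None = None,
    aes: Aes | None = None,
    range_geom: str = "rect",
    gap_geom: str = "chevron",
    height: float = 0.8,
    min_gap: int = 0,
    apex_offset: float = 0.25,
) -> Layer:
    def build(d: RangeTable) -> list[Primitive]:
        return geoms.geom_alignment(
            d, aes, range_geom=range_geom, gap_geom=gap_geom,
            height=height, min_gap=min_gap, apex_offset=apex_offset,
        )

    return Layer(name="alignment", build=build, data=data)


def layer_area(data: CoverageRLE | None = None, aes: Aes | None = None) -> Layer:
    def build(d: CoverageRLE) -> list[Primitive]:
        return geoms.geom_coverage_area(d, aes)

    return Layer(name="area", build=build, data=data)


def layer_arch(
    data: RangeTable | None = None,
    aes: Aes | None = None,
    height_scale: float = 0.3,
    base: float = 0.0,
) -> Layer:
    def build(d: RangeTable) -> list[Primitive]:
        return geoms.geom_arch(d, aes, height_scale=height_scale, base=base)

    return Layer(name="arch", build=build, data=data)


def layer_mismatch(data=None) -> Layer:
    def build(d) -> list[Primitive]:
        return geoms.geom_mismatch_bars(d)

    return Layer(name="mismatch", build=build, data=data)


def layer_points(data: pd.DataFrame | None = None, size: float = 2.0) -> Layer:
    """Points from a DataFrame with columns x, y and optional fill."""

    def build(d: pd.DataFrame) -> list[Primitive]:
        fills = d["fill"] if "fill" in d.columns else [geoms.PALETTE[0]] * len(d)
        return [
            Primitive(
                "point", ((float(x), float(y)),),
                {"fill": f, "size": size, "class": "point"}, group=i,
            )
            for i, (x, y, f) in enumerate(zip(d["x"], d["y"], fills))
        ]

    return Layer(name="points", build=build, data=data)


def layer_primitives(prims: Sequence[Primitive], name: str = "primitives") -> Layer:
    """A layer wrapping a precomputed primitive list."""
    frozen = list(prims)
    return Layer(name=name, build=lambda _d: list(frozen), data=frozen)


# ---------------------------------------------------------------------------
# PlotSpec and composition


@dataclass(frozen=True)
class PlotSpec:
    data: Any = None
    layers: tuple[Layer, ...] = ()
    coord: Coord = field(default_factory=Coord)
    layout: str = "linear"
    theme: Theme = field(default_factory=Theme)
    panels: tuple[PanelPlacement, ...] | None = None
    panel_data: Mapping[str, Any] | None = None
    x_domain: tuple[float, float] | None = None

    def __add__(self, element) -> "PlotSpec":
        return compose(self, element)


def empty_plot(data: Any = None) -> PlotSpec:
    """An empty plot to compose layers onto (the low-level entry point)."""
    return PlotSpec(data=data)


def compose(plot: PlotSpec, element) -> PlotSpec:
    """Add an element to a plot, returning a new spec (input unchanged).

    Layers append in order; a Coord or Theme replaces the current one.
    """
    if isinstance(element, Layer):
        return replace(plot, layers=plot.layers + (element,))
    if isinstance(element, Coord):
        return replace(plot, coord=element)
    if isinstance(element, Theme):
        return replace(plot, theme=element)
    raise TypeError(f"cannot compose a {type(element).__name__} onto a plot")


def build_primitives(spec: PlotSpec, data: Any = None) -> list[Primitive]:
    """Evaluate all layers in order against the plot (or panel) data."""
    out: list[Primitive] = []
    base = data if data is not None else spec.data
    for layer in spec.layers:
        d = layer.data if layer.data is not None else base
        out.extend(layer.build(d))
    return out


# ---------------------------------------------------------------------------
# autoplot dispatch


def _auto_range_table(data: RangeTable, mapping, options) -> PlotSpec:
    if data.group_key is not None:
        return PlotSpec(
            data=data,
            layers=(
                layer_alignment(
                    aes=mapping,
                    range_geom=options.get("range_geom", "rect"),
                    gap_geom=options.get("gap_geom", "chevron"),
                    height=options.get("height", 0.8),
                    min_gap=options.get("min_gap", 0),
                ),
            ),
        )
    return PlotSpec(data=data, layers=(layer_rect(aes=mapping),))


def _auto_alignment_table(data: AlignmentTable, mapping, options) -> PlotSpec:
    kind = options.get("plot", "reads")
    if kind == "coverage":
        cov = stat_coverage(data.blocks_table(group_by_read=False))
        return PlotSpec(data=cov, layers=(layer_area(),))
    return PlotSpec(
        data=data.blocks_table(),
        layers=(layer_alignment(aes=mapping, gap_geom="segment"),),
    )


def _auto_coverage(data: CoverageRLE, mapping, options) -> PlotSpec:
    return PlotSpec(data=data, layers=(layer_area(aes=mapping),))


#: autoplot dispatch table: (type, builder(data, aes, options)) pairs,
#: checked in order.  Extend with :func:`register_autoplot`.
AUTOPLOT_REGISTRY: list[tuple[type, Callable]] = [
    (RangeTable, _auto_range_table),
    (AlignmentTable, _auto_alignment_table),
    (CoverageRLE, _auto_coverage),
]


def register_autoplot(dtype: type, builder: Callable) -> None:
    AUTOPLOT_REGISTRY.insert(0, (dtype, builder))


def autoplot(data: Any, aes: Aes | None = None, **options) -> PlotSpec:
    """Recognise the data structure and build the appropriate plot."""
    for dtype, builder in AUTOPLOT_REGISTRY:
        if isinstance(data, dtype):
            return builder(data, aes, options)
    raise TypeError(f"autoplot cannot dispatch on {type(data).__name__}")


# ---------------------------------------------------------------------------
# tracks


def _plot_seqname(plot: PlotSpec) -> str | None:
    d = plot.data
    if isinstance(d, RangeTable) and len(d):
        seqs = set(d.seqnames)
        if len(seqs) == 1:
            return seqs.pop()
    if isinstance(d, CoverageRLE):
        return d.seqname
    return None


def _plot_x_hull(plot: PlotSpec) -> tuple[float, float] | None:
    prims = build_primitives(plot)
    if not prims:
        return None
    lo = min(p.x_extent[0] for p in prims)
    hi = max(p.x_extent[1] for p in prims)
    return lo, hi


@dataclass(frozen=True)
class TrackStack:
    """Ordered plots sharing one x axis, with relative heights."""

    plots: tuple[PlotSpec, ...]
    heights: tuple[float, ...]
    xlim: tuple[float, float] | None = None
    seqname: str | None = None

    def shared_x_domain(self) -> tuple[float, float]:
        if self.xlim is not None:
            return self.xlim
        hulls = [h for h in (_plot_x_hull(p) for p in self.plots) if h is not None]
        if not hulls:
            return (0.0, 1.0)
        return min(h[0] for h in hulls), max(h[1] for h in hulls)


def tracks(
    plots: Sequence[PlotSpec], heights: Sequence[float] | None = None
) -> TrackStack:
    """Stack plots top-to-bottom over a shared x-domain.

    Page heights are allocated in the ratio of ``heights`` (default: equal).
    The shared x-domain is the union of the member x-domains unless
    overridden by :func:`zoom_shift`.
    """
    plots = tuple(plots)
    if heights is None:
        heights = [1.0] * len(plots)
    heights = tuple(float(h) for h in heights)
    if len(heights) != len(plots):
        raise ValueError("heights must match plots in length")
    if any(h <= 0 for h in heights):
        raise ValueError("heights must be positive")
    seqnames = {s for s in (_plot_seqname(p) for p in plots) if s is not None}
    seqname = seqnames.pop() if len(seqnames) == 1 else None
    return TrackStack(plots=plots, heights=heights, seqname=seqname)


def zoom_shift(
    stack: TrackStack,
    window: GenomicRange | None = None,
    factor: float | None = None,
    shift: float = 0.0,
) -> TrackStack:
    """Zoom (to a window or by a factor about the centre) and/or shift.

    Returns a new stack; the original is unchanged.  A window on a
    different seqname than the stack's data is an error.
    """
    lo, hi = stack.shared_x_domain()
    if window is not None:
        if stack.seqname is not None and window.seqname != stack.seqname:
            raise ValueError(
                f"window on {window.seqname!r} but tracks on {stack.seqname!r}"
            )
        lo, hi = float(window.start), float(window.end)
    if factor is not None:
        if factor <= 0:
            raise ValueError("zoom factor must be positive")
        cx = (lo + hi) / 2.0
        half = (hi - lo) / (2.0 * factor)
        lo, hi = cx - half, cx + half
    lo, hi = lo + shift, hi + shift
    if lo >= hi:
        raise ValueError("empty window after zoom/shift")
    return replace(stack, xlim=(lo, hi))


# ---------------------------------------------------------------------------
# high-level figure builders


def manhattan_plot(
    scores: pd.DataFrame,
    seqinfo: SeqInfo,
    mode: str = "proportional",
    buffer: float = 0.0,
    k: int = 5,
    stat: str = "mean",
    point_size: float = 2.0,
) -> PlotSpec:
    """Grand linear (Manhattan) view of a per-position score table.

    ``scores`` has columns ``chr``, ``pos``, ``value`` and optionally
    ``group`` (faceted into one panel per group).  Values are aggregated
    over sliding windows of ``k`` consecutive positions per chromosome and
    plotted against global genomic coordinates from the genome
    concatenation map; chromosomes alternate between two colors so their
    boundaries read as stripes.
    """
    gmap = build_genome_map(seqinfo, mode=mode, buffer=buffer)
    groups = list(dict.fromkeys(scores["group"])) if "group" in scores.columns else [None]
    panels: list[PanelPlacement] = []
    panel_data: dict[str, pd.DataFrame] = {}
    stripe = (geoms.PALETTE[0], geoms.PALETTE[4])
    for gi, g in enumerate(groups):
        sub = scores if g is None else scores[scores["group"] == g]
        table = make_range_table(
            [(c, p, p) for c, p in zip(sub["chr"], sub["pos"])],
            metadata={"value": list(sub["value"])},
            seqinfo=seqinfo,
        )
        ws = stat_aggregate(table, "value", k=k, stat=stat)
        xs, ys, fills = [], [], []
        for w in ws:
            mid = min(max((w.start + w.end) // 2, 1), seqinfo.length(w.seqname))
            xs.append(genome_to_global(gmap, (w.seqname, mid)))
            ys.append(w.value)
            fills.append(stripe[seqinfo.index(w.seqname) % 2])
        label = str(g) if g is not None else "scores"
        panel_data[label] = pd.DataFrame({"x": xs, "y": ys, "fill": fills})
        panels.append(
            PanelPlacement(
                panel=label, row=gi + 1, col=1,
                x_domain=(0.0, gmap.total_span),
                extent=(0.0, float(gi), 1.0, 1.0),
            )
        )
    return PlotSpec(
        data=None, layers=(layer_points(size=point_size),), layout="linear",
        panels=tuple(panels), panel_data=panel_data,
    )


def karyogram_plot(
    seqinfo: SeqInfo,
    features: RangeTable | None = None,
    cytobands: RangeTable | None = None,
    ncol: int = 1,
) -> PlotSpec:
    """Karyogram overview: chromosomes as an array of scaled rectangles."""
    placements = layout_karyogram(seqinfo, ncol=ncol)
    panel_data: dict[str, Any] = {}
    for seqname, length in seqinfo.entries:
        feat = None
        if features is not None:
            feat = features.subset(features.df["seqname"].to_numpy() == seqname)
        cyto = None
        if cytobands is not None:
            cyto = cytobands.subset(cytobands.df["seqname"].to_numpy() == seqname)
        panel_data[seqname] = {"length": length, "features": feat, "cytobands": cyto}

    def build(d: Mapping[str, Any]) -> list[Primitive]:
        prims: list[Primitive] = []
        if d["cytobands"] is not None and len(d["cytobands"]):
            prims += geoms.geom_ideogram(d["cytobands"])
        else:
            prims.append(
                Primitive(
                    "rect", ((1.0, 0.0), (float(d["length"]), 1.0)),
                    {"fill": "none", "stroke": "#000000", "class": "chromosome"},
                    group="chromosome",
                )
            )
        feat = d["features"]
        if feat is not None and len(feat):
            prims += geoms.geom_rect(feat, None, y=0.5, height=0.8)
        return prims

    return PlotSpec(
        data=None, layers=(Layer(name="karyogram", build=build),),
        layout="karyogram", panels=tuple(placements), panel_data=panel_data,
    )


def circular_plot(
    seqinfo: SeqInfo,
    links: pd.DataFrame | None = None,
    mode: str = "proportional",
    start_angle: float = 0.0,
    gap_degrees: float = 5.0,
    inner_radius: float = 80.0,
    outer_radius: float = 100.0,
    curvature: float = 0.2,
) -> PlotSpec:
    """Circular overview: ideogram ring plus curved links between loci.

    Links (columns chr1, pos1, chr2, pos2, score, support) are drawn as
    quadratic Beziers on the inner radius; intrachromosomal links in green,
    interchromosomal in orange, stroke width from the support count on a
    square-root scale.
    """
    import math

    gmap = build_genome_map(seqinfo, mode=mode)
    ring = make_ring(
        gmap, ring_index=0, inner_radius=inner_radius, outer_radius=outer_radius,
        start_angle=start_angle, gap_degrees=gap_degrees,
    )
    prims: list[Primitive] = []

    def xy(angle: float, radius: float) -> tuple[float, float]:
        rad = math.radians(angle)
        return radius * math.sin(rad), radius * math.cos(rad)

    for seqname, arc_start, span in ring.spans:
        n_steps = max(int(span), 2)
        angles = [
            ring.start_angle + ring.direction * (arc_start + span * i / n_steps)
            for i in range(n_steps + 1)
        ]
        outer = [xy(a, ring.outer_radius) for a in angles]
        inner = [xy(a, ring.inner_radius) for a in reversed(angles)]
        prims.append(
            Primitive(
                "polygon", tuple(outer + inner),
                {"fill": "#DDDDDD", "stroke": "#555555", "class": "arc"},
                group=seqname,
            )
        )
        mid_a = ring.start_angle + ring.direction * (arc_start + span / 2.0)
        lx, ly = xy(mid_a, ring.outer_radius + 12.0)
        prims.append(
            Primitive(
                "text", ((lx, ly),),
                {"text": seqname, "class": "label"}, group=seqname,
            )
        )
    link_colors = {"intra": "#009E73", "inter": "#E69F00"}
    if links is not None:
        for i, row in enumerate(links.itertuples(index=False)):
            lp = link_path(
                ring, gmap, (row.chr1, row.pos1), (row.chr2, row.pos2),
                curvature=curvature,
            )
            p0, p1 = lp.xy
            size = max(0.5, math.sqrt(float(getattr(row, "support", 1.0))))
            prims.append(
                Primitive(
                    "bezier", (p0, lp.control, p1),
                    {"stroke": link_colors[lp.class_label], "size": size,
                     "class": f"link-{lp.class_label}"},
                    group=i,
                )
            )
    return PlotSpec(
        data=None, layers=(layer_primitives(prims, name="circular"),),
        layout="circular",
    )
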