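"""Deterministic SVG rendering of plot specs and track stacks.

The renderer is a pure function of the spec: the same spec always yields
byte-identical SVG.  Every data primitive becomes exactly one SVG element
carrying its group id in a ``data-group`` attribute and its geom class in
``class``, so rendered output is machine-checkable.  Decoration (panel
background, axes, legend) carries no ``data-group``.

Primitive x coordinates pass through the plot's coordinate transform
(e.g. gap truncation) before page scaling, and are clipped to the panel's
x-domain so no element escapes its panel.
"""

from __future__ import annotations

from typing import Any, Sequence
from xml.sax.saxutils import escape

from .geoms import Primitive
from .plot import PlotSpec, TrackStack, build_primitives

__all__ = ["render_svg", "render_svg_string"]

_MARGIN = 40.0
_PANEL_PAD = 6.0


def _fmt(v: float) -> str:
    s = f"{float(v):.3f}"
    s = s.rstrip("0").rstrip(".")
    return "0" if s in ("-0", "") else s


def _aes_attrs(p: Primitive) -> str:
    a = p.aes
    parts = []
    if p.kind in ("rect", "polygon", "point"):
        parts.append(f'fill="{a.get("fill", "#333333")}"')
        if "stroke" in a:
            parts.append(f'stroke="{a["stroke"]}"')
    elif p.kind in ("polyline", "bezier"):
        parts.append('fill="none"')
        parts.append(f'stroke="{a.get("stroke", "#333333")}"')
    if "size" in a and p.kind in ("polyline", "bezier", "rect", "polygon"):
        parts.append(f'stroke-width="{_fmt(float(a["size"]))}"')
    if "alpha" in a:
        parts.append(f'opacity="{_fmt(float(a["alpha"]))}"')
    parts.append(f'class="{a.get("class", p.kind)}"')
    if p.group is not None:
        parts.append(f'data-group="{escape(str(p.group))}"')
    return " ".join(parts)


def _emit(p: Primitive, tx, ty) -> str:
    pts = [(tx(x), ty(y)) for x, y in p.points]
    attrs = _aes_attrs(p)
    if p.kind == "rect":
        (x1, y1), (x2, y2) = pts
        x, y = min(x1, x2), min(y1, y2)
        w, h = abs(x2 - x1), abs(y2 - y1)
        return (
            f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" '
            f'height="{_fmt(h)}" {attrs}/>'
        )
    if p.kind in ("polyline", "polygon"):
        coords = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
        return f'<{p.kind} points="{coords}" {attrs}/>'
    if p.kind == "bezier":
        (x0, y0), (cx, cy), (x1, y1) = pts
        d = (
            f"M {_fmt(x0)} {_fmt(y0)} Q {_fmt(cx)} {_fmt(cy)} "
            f"{_fmt(x1)} {_fmt(y1)}"
        )
        return f'<path d="{d}" {attrs}/>'
    if p.kind == "point":
        (x, y), = pts
        r = float(p.aes.get("size", 2.0))
        return f'<circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(r)}" {attrs}/>'
    if p.kind == "text":
        (x, y), = pts
        return (
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="10" {attrs}>'
            f"{escape(str(p.aes.get('text', '')))}</text>"
        )
    raise ValueError(f"unknown primitive kind {p.kind!r}")


def _clip_x(prims: Sequence[Primitive], lo: float, hi: float) -> list[Primitive]:
    """Clamp primitive x coordinates into [lo, hi]; drop fully-outside ones."""
    out = []
    for p in prims:
        xlo, xhi = p.x_extent
        if xhi < lo or xlo > hi:
            continue
        if xlo >= lo and xhi <= hi:
            out.append(p)
            continue
        pts = tuple((min(max(x, lo), hi), y) for x, y in p.points)
        out.append(Primitive(p.kind, pts, dict(p.aes), p.group))
    return out


def _y_range(prims: Sequence[Primitive]) -> tuple[float, float]:
    ys = [y for p in prims for _, y in p.points]
    if not ys:
        return 0.0, 1.0
    lo, hi = min(ys), max(ys)
    if hi - lo < 1e-12:
        lo, hi = lo - 0.5, hi + 0.5
    pad = 0.05 * (hi - lo)
    return lo - pad, hi + pad


def _render_panel(
    lines: list[str],
    spec: PlotSpec,
    prims: list[Primitive],
    x_domain: tuple[float, float],
    px: float, py: float, pw: float, ph: float,
    title: str | None,
    legend_entries: dict[str, str],
) -> None:
    theme = spec.theme
    band_y, band_h = py, ph  # full band; data area is padded inside it
    py, ph = py + _PANEL_PAD, max(ph - 2 * _PANEL_PAD, 1.0)
    xlo, xhi = x_domain
    if xhi - xlo < 1e-12:
        xlo, xhi = xlo - 0.5, xhi + 0.5
    # coordinate transform, then clip to the transformed panel domain
    if spec.coord.kind != "identity":
        prims = [
            Primitive(
                p.kind,
                tuple((spec.coord.forward(x), y) for x, y in p.points),
                dict(p.aes), p.group,
            )
            for p in prims
        ]
        xlo, xhi = spec.coord.forward(xlo), spec.coord.forward(xhi)
    prims = _clip_x(prims, xlo, xhi)
    ylo, yhi = _y_range(prims)

    def tx(x: float) -> float:
        return px + (x - xlo) / (xhi - xlo) * pw

    def ty(y: float) -> float:
        return py + ph - (y - ylo) / (yhi - ylo) * ph

    if theme.background:
        lines.append(
            f'<rect x="{_fmt(px)}" y="{_fmt(band_y)}" width="{_fmt(pw)}" '
            f'height="{_fmt(band_h)}" fill="#F7F7F7" class="background"/>'
        )
    lines.append('<g class="axes">')
    lines.append(
        f'<line x1="{_fmt(px)}" y1="{_fmt(py + ph)}" x2="{_fmt(px + pw)}" '
        f'y2="{_fmt(py + ph)}" stroke="#222222"/>'
    )
    if theme.axis_labels:
        lines.append(
            f'<text x="{_fmt(px)}" y="{_fmt(py + ph + 12)}" font-size="9" '
            f'class="tick">{_fmt(xlo)}</text>'
        )
        lines.append(
            f'<text x="{_fmt(px + pw)}" y="{_fmt(py + ph + 12)}" font-size="9" '
            f'text-anchor="end" class="tick">{_fmt(xhi)}</text>'
        )
        if title:
            lines.append(
                f'<text x="{_fmt(px + 2)}" y="{_fmt(py + 10)}" font-size="10" '
                f'class="panel-title">{escape(title)}</text>'
            )
    lines.append("</g>")
    for p in prims:
        lines.append(_emit(p, tx, ty))
        label = p.aes.get("legend_label")
        if label is not None:
            color = p.aes.get("fill") or p.aes.get("stroke") or "#333333"
            legend_entries.setdefault(str(label), color)


def _render_plot(
    lines: list[str],
    spec: PlotSpec,
    x0: float, y0: float, width: float, height: float,
    x_domain: tuple[float, float] | None,
    legend_entries: dict[str, str],
) -> None:
    if spec.panels is None:
        prims = build_primitives(spec)
        if x_domain is None:
            x_domain = spec.x_domain
        if x_domain is None:
            if prims:
                x_domain = (
                    min(p.x_extent[0] for p in prims),
                    max(p.x_extent[1] for p in prims),
                )
            else:
                x_domain = (0.0, 1.0)
        _render_panel(
            lines, spec, prims, x_domain, x0, y0, width, height,
            None, legend_entries,
        )
        return
    # multi-panel: scale panel extents (grid units) onto the page area
    max_x = max(p.extent[0] + p.extent[2] for p in spec.panels)
    max_y = max(p.extent[1] + p.extent[3] for p in spec.panels)
    # grid cell span includes full cell width even for short karyogram panels
    ncols = max(p.col for p in spec.panels)
    nrows = max(p.row for p in spec.panels)
    max_x = max(max_x, float(ncols))
    max_y = max(max_y, float(nrows))
    for panel in spec.panels:
        ex, ey, ew, eh = panel.extent
        px = x0 + ex / max_x * width
        py = y0 + ey / max_y * height
        pw = ew / max_x * width
        ph = eh / max_y * height
        data = None
        if spec.panel_data is not None:
            data = spec.panel_data.get(panel.panel)
        prims = build_primitives(spec, data=data) if data is not None else (
            build_primitives(spec)
        )
        dom = x_domain if x_domain is not None else panel.x_domain
        _render_panel(
            lines, spec, prims, dom,
            px, py, pw, ph, str(panel.panel), legend_entries,
        )


def render_svg_string(
    target: PlotSpec | TrackStack, page: tuple[float, float] = (800.0, 500.0)
) -> str:
    """Render a plot or track stack to an SVG document string."""
    width, height = float(page[0]), float(page[1])
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
    ]
    legend_entries: dict[str, str] = {}
    inner_w = width - 2 * _MARGIN
    inner_h = height - 2 * _MARGIN
    if isinstance(target, TrackStack):
        shared = target.shared_x_domain()
        total = sum(target.heights)
        cursor = _MARGIN
        show_legend = any(p.theme.legend for p in target.plots)
        for plot, h in zip(target.plots, target.heights):
            band = inner_h * h / total
            _render_plot(
                lines, plot, _MARGIN, cursor, inner_w, band, shared,
                legend_entries,
            )
            cursor += band
    elif isinstance(target, PlotSpec):
        show_legend = target.theme.legend
        _render_plot(
            lines, target, _MARGIN, _MARGIN, inner_w, inner_h, None,
            legend_entries,
        )
    else:
        raise TypeError(f"cannot render a {type(target).__name__}")
    if show_legend and legend_entries:
        lines.append('<g class="legend">')
        for i, (label, color) in enumerate(legend_entries.items()):
            y = 14.0 + 14.0 * i
            lines.append(
                f'<rect x="{_fmt(width - 110)}" y="{_fmt(y - 8)}" width="10" '
                f'height="10" fill="{color}"/>'
            )
            lines.append(
                f'<text x="{_fmt(width - 96)}" y="{_fmt(y)}" font-size="10">'
                f"{escape(label)}</text>"
            )
        lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def render_svg(
    target: PlotSpec | TrackStack,
    path,
    page: tuple[float, float] = (800.0, 500.0),
) -> str:
    """Render to SVG and write the file; returns the document string."""
    doc = render_svg_string(target, page=page)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(doc)
    return doc
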