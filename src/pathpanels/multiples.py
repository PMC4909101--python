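"""Replicate the styled map once per sample and compose the SVG.

The small-multiples idea: every panel is the *same* map — same node
positions, same sizes — and only fill colors (and, under the hide policy,
visibility) differ between panels, so differences across samples are read
by eye.  Panels are arranged row-major on a grid and written as one
standalone SVG 1.1 document with a shared legend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from xml.etree import ElementTree as ET

from .binding import BindingResult, BindingSpec
from .model import Edge, NetworkMap, PathPanelsError
from .styling import NodeAppearance, VisualStyle, node_appearance


@dataclass(frozen=True)
class Panel:
    """One styled replica of the map, for one sample."""

    title: str
    appearances: dict[str, NodeAppearance]
    visible_edges: tuple[Edge, ...]


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry for panel placement, in canvas units."""

    n_cols: int | str = "auto"
    panel_gap: float = 24.0
    margin: float = 16.0
    title_height: float = 22.0

    def __post_init__(self) -> None:
        if self.n_cols != "auto" and (not isinstance(self.n_cols, int) or self.n_cols < 1):
            raise ValueError(f"n_cols must be a positive integer or 'auto', got {self.n_cols!r}")
        if self.panel_gap < 0 or self.margin < 0 or self.title_height < 0:
            raise ValueError("panel_gap, margin and title_height must be >= 0")

    def columns_for(self, k: int) -> int:
        if self.n_cols == "auto":
            return max(1, math.ceil(math.sqrt(k)))
        return self.n_cols


@dataclass(frozen=True)
class RenderedDocument:
    svg_text: str
    width: float
    height: float


def resolve_vmax(style: VisualStyle, binding: BindingResult) -> float:
    """The shared gradient scale: explicit ``value_max``, or the maximum
    absolute value over *all* series jointly so every panel is comparable."""
    if style.value_max != "auto":
        return float(style.value_max)
    peak = max(
        (abs(d.value) for per_series in binding.series_data.values() for d in per_series.values()),
        default=0.0,
    )
    return peak if peak > 0 else 1.0


def build_panels(
    network: NetworkMap,
    binding: BindingResult,
    spec: BindingSpec,
    style: VisualStyle,
) -> list[Panel]:
    """One panel per series, in series order.

    Each panel styles every map node via :func:`styling.node_appearance`
    against that series' bound data; edges touching a hidden node are
    excluded from the panel (hiding a node hides its edges).
    """
    if not spec.series:
        raise PathPanelsError("no samples to render")
    vmax = resolve_vmax(style, binding)
    panels: list[Panel] = []
    for series in spec.series:
        data = binding.series_data.get(series.name, {})
        appearances = {
            node.node_id: node_appearance(node, data.get(node.node_id), style, vmax)
            for node in network.nodes
        }
        visible_edges = tuple(
            e for e in network.edges
            if appearances[e.source].visible and appearances[e.target].visible
        )
        panels.append(Panel(title=series.name, appearances=appearances,
                            visible_edges=visible_edges))
    return panels


def layout_grid(
    k: int,
    template_extent: tuple[float, float],
    grid: GridSpec,
) -> list[tuple[float, float]]:
    """Row-major panel origins (top-left of each panel's map area).

    ``n_cols="auto"`` uses ceil(sqrt(k)); each grid cell reserves
    ``title_height`` above the map area for the panel title.
    """
    if k < 1:
        raise ValueError("need at least one panel")
    width, height = template_extent
    n_cols = grid.columns_for(k)
    cell_w = width + grid.panel_gap
    cell_h = height + grid.title_height + grid.panel_gap
    origins = []
    for i in range(k):
        row, col = divmod(i, n_cols)
        origins.append((
            grid.margin + col * cell_w,
            grid.margin + grid.title_height + row * cell_h,
        ))
    return origins


def _fmt(x: float) -> str:
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _edge_endpoints(network: NetworkMap, edge: Edge) -> tuple[float, float, float, float]:
    """Straight segment between node centers, clipped at the node borders."""
    nodes = network.node_by_id
    a, b = nodes[edge.source], nodes[edge.target]
    dx, dy = b.x - a.x, b.y - a.y
    length = math.hypot(dx, dy)
    if length == 0:
        return a.x, a.y, b.x, b.y

    def border_t(node) -> float:
        tx = (node.width / 2) / abs(dx) if dx else math.inf
        ty = (node.height / 2) / abs(dy) if dy else math.inf
        return min(tx, ty)

    ta = min(border_t(a), 0.5)
    tb = min(border_t(b), 0.5)
    return (
        a.x + dx * ta, a.y + dy * ta,
        b.x - dx * tb, b.y - dy * tb,
    )


_FONT = "sans-serif"


def render_svg(
    panels: list[Panel],
    network: NetworkMap,
    grid: GridSpec = GridSpec(),
    style: VisualStyle = VisualStyle(),
) -> RenderedDocument:
    """Compose the panels into one standalone SVG document.

    Structure: one ``<g class="panel">`` per panel (title text, edge lines,
    one rounded rectangle + centered label per visible node) plus a single
    ``<g class="legend">`` with the up/neutral/down anchors and the no-data
    swatch.  Output is deterministic: the same inputs yield byte-identical
    SVG text.
    """
    if not panels:
        raise PathPanelsError("no samples to render")
    extent = network.extent
    origins = layout_grid(len(panels), extent, grid)
    n_cols = grid.columns_for(len(panels))
    n_rows = math.ceil(len(panels) / n_cols)
    legend_height = 34.0
    doc_w = 2 * grid.margin + n_cols * extent[0] + (n_cols - 1) * grid.panel_gap
    doc_h = (2 * grid.margin + n_rows * (extent[1] + grid.title_height)
             + (n_rows - 1) * grid.panel_gap + legend_height)

    root = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": _fmt(doc_w),
        "height": _fmt(doc_h),
        "viewBox": f"0 0 {_fmt(doc_w)} {_fmt(doc_h)}",
    })
    nodes = network.node_by_id
    for panel, (ox, oy) in zip(panels, origins):
        g = ET.SubElement(root, "g", {
            "class": "panel",
            "transform": f"translate({_fmt(ox)},{_fmt(oy)})",
        })
        title = ET.SubElement(g, "text", {
            "class": "panel-title",
            "x": _fmt(extent[0] / 2),
            "y": _fmt(-grid.title_height / 3),
            "text-anchor": "middle",
            "font-family": _FONT,
            "font-size": "13",
            "font-weight": "bold",
        })
        title.text = panel.title
        for edge in panel.visible_edges:
            x1, y1, x2, y2 = _edge_endpoints(network, edge)
            ET.SubElement(g, "line", {
                "x1": _fmt(x1), "y1": _fmt(y1),
                "x2": _fmt(x2), "y2": _fmt(y2),
                "stroke": "#000000", "stroke-width": "1",
            })
        for node in network.nodes:
            appearance = panel.appearances[node.node_id]
            if not appearance.visible:
                continue
            ET.SubElement(g, "rect", {
                "x": _fmt(node.x - node.width / 2),
                "y": _fmt(node.y - node.height / 2),
                "width": _fmt(node.width),
                "height": _fmt(node.height),
                "rx": "4",
                "fill": appearance.fill,
                "stroke": "#404040",
                "stroke-width": "1",
            })
            if node.label:
                text = ET.SubElement(g, "text", {
                    "x": _fmt(node.x),
                    "y": _fmt(node.y),
                    "text-anchor": "middle",
                    "dominant-baseline": "central",
                    "font-family": _FONT,
                    "font-size": "10",
                })
                text.text = node.label

    legend = ET.SubElement(root, "g", {
        "class": "legend",
        "transform": f"translate({_fmt(grid.margin)},{_fmt(doc_h - legend_height + 6)})",
    })
    swatches = [
        ("up", style.up_color),
        ("neutral", style.neutral_color),
        ("down", style.down_color),
        ("no data", style.no_data_color),
    ]
    for i, (label, color) in enumerate(swatches):
        x = i * 90.0
        ET.SubElement(legend, "rect", {
            "x": _fmt(x), "y": "0", "width": "16", "height": "16",
            "fill": color, "stroke": "#404040", "stroke-width": "1",
        })
        text = ET.SubElement(legend, "text", {
            "x": _fmt(x + 22), "y": "12",
            "font-family": _FONT, "font-size": "11",
        })
        text.text = label

    svg_text = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        + ET.tostring(root, encoding="unicode")
        + "\n"
    )
    return RenderedDocument(svg_text=svg_text, width=doc_w, height=doc_h)
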