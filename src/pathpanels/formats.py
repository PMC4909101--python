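"""Readers and writers for the supported input formats.

Pathway maps come in as GPML (the WikiPathways / PathVisio XML dialect,
2013a namespace); plain networks as SIF or GraphML.  Measurement tables are
delimited text with a mandatory header row; the separator can be sniffed
from the first few lines or given explicitly.

Coordinates are taken as-is from GPML (origin top-left, y down — the SVG
convention) except for a uniform translation that moves the map's bounding
box to (0, 0).  Formats that carry no geometry (SIF, GraphML without
position keys) get a deterministic circular layout.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from typing import Literal

import networkx as nx
from lxml import etree

from .model import (
    DataTable,
    Edge,
    NetworkMap,
    Node,
    NodeKind,
    ParseError,
    normalized,
)

logger = logging.getLogger(__name__)

GPML_NS = "http://pathvisio.org/GPML/2013a"

Separator = Literal["comma", "semicolon", "tab", "whitespace"]

#: Sniffing precedence (used only to break ties between equally good candidates).
_SEPARATOR_PRECEDENCE: tuple[Separator, ...] = ("tab", "comma", "semicolon", "whitespace")

_SEPARATOR_CHARS = {"comma": ",", "semicolon": ";", "tab": "\t"}


def _split_line(line: str, separator: Separator) -> list[str]:
    if separator == "whitespace":
        return line.split()
    char = _SEPARATOR_CHARS[separator]
    # csv handles quoted fields for single-character separators
    return next(csv.reader([line], delimiter=char))


def detect_separator(sample_text: str) -> Separator:
    """Guess the field separator from the first lines of a file.

    Each candidate separator is scored by the column count it produces,
    provided that count is >= 2 and consistent across the sampled non-empty
    lines; the candidate with the most columns wins, ties resolved
    tab > comma > semicolon > whitespace.

    Raises :class:`ParseError` if no candidate yields at least two
    consistent columns.
    """
    if not sample_text.strip():
        raise ParseError("undetectable separator: empty input")
    lines = [ln for ln in sample_text.splitlines() if ln.strip()][:10]
    best: Separator | None = None
    best_count = 0
    for candidate in _SEPARATOR_PRECEDENCE:
        counts = {len(_split_line(ln, candidate)) for ln in lines}
        if len(counts) != 1:
            continue
        (count,) = counts
        if count >= 2 and count > best_count:
            best, best_count = candidate, count
    if best is None:
        raise ParseError("undetectable separator: no candidate yields >= 2 consistent columns")
    return best


def parse_delimited_table(
    text: str,
    separator: Separator,
    id_column: str = "first",
    source: str = "<string>",
) -> DataTable:
    """Parse delimited text (header + rows) into a :class:`DataTable`.

    Numeric cells become floats; empty, non-numeric or non-finite cells in
    value columns become missing (``None``).  Rows whose cell count differs
    from the header are a parse error naming the 1-based line number.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{source}: empty file")
    header = [c.strip() for c in _split_line(lines[0], separator)]
    if len(lines) == 1:
        raise ParseError(f"{source}: header-only file (no data rows)")
    if len(set(header)) != len(header):
        raise ParseError(f"{source}: duplicate column names in header")
    if id_column == "first":
        id_name = header[0]
    else:
        if id_column not in header:
            raise ParseError(f"{source}: identifier column {id_column!r} not in header")
        id_name = id_column
    id_index = header.index(id_name)

    rows: list[tuple[str, tuple[float | None, ...]]] = []
    line_numbers: list[int] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in _split_line(raw, separator)]
        if len(cells) != len(header):
            raise ParseError(
                f"{source}: line {lineno}: expected {len(header)} fields, got {len(cells)}"
            )
        identifier = cells[id_index]
        if not identifier:
            raise ParseError(f"{source}: line {lineno}: empty identifier cell")
        values = tuple(
            _parse_number(cell)
            for i, cell in enumerate(cells)
            if i != id_index
        )
        rows.append((identifier, values))
        line_numbers.append(lineno)
    columns = [id_name] + [c for i, c in enumerate(header) if i != id_index]
    return DataTable(id_column=id_name, columns=columns, rows=rows, line_numbers=line_numbers)


def _parse_number(cell: str) -> float | None:
    if not cell:
        return None
    try:
        value = float(cell)
    except ValueError:
        return None
    return value if math.isfinite(value) else None


def read_delimited_table(
    path: str,
    separator: Separator | Literal["auto"] = "auto",
    id_column: str = "first",
) -> DataTable:
    """Read a delimited measurement table from a file.

    With ``separator="auto"`` the separator is sniffed from the first ten
    lines via :func:`detect_separator`.
    """
    with open(path, encoding="utf-8", newline="") as handle:
        text = handle.read()
    if separator == "auto":
        sample = "\n".join(text.splitlines()[:10])
        separator = detect_separator(sample)
        logger.info("detected separator: %s", separator)
    return parse_delimited_table(text, separator, id_column=id_column, source=path)


# ---------------------------------------------------------------------------
# GPML
# ---------------------------------------------------------------------------

def _q(tag: str) -> str:
    return f"{{{GPML_NS}}}{tag}"


def read_gpml(stream: str | bytes) -> NetworkMap:
    """Parse GPML text into a :class:`NetworkMap`.

    DataNode elements become bindable data nodes (label from ``TextLabel``,
    geometry from the ``Graphics`` child, Xref carried in the attribute
    map); Label and Shape elements become decorations.  Interaction and
    GraphicalLine elements whose first and last points reference node
    GraphIds become edges; references to unknown GraphIds (e.g. anchors)
    are dropped with a logged warning.  Group containers are ignored and
    their member nodes kept.
    """
    if isinstance(stream, str):
        stream = stream.encode("utf-8")
    try:
        root = etree.fromstring(stream)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not well-formed XML: {exc}") from exc
    if etree.QName(root).namespace != GPML_NS:
        raise ParseError(
            f"root element is not in the GPML namespace {GPML_NS!r} "
            f"(got {etree.QName(root).namespace!r})"
        )

    nodes: list[Node] = []
    node_ids: set[str] = set()
    auto_id = 0

    def fresh_id(prefix: str) -> str:
        nonlocal auto_id
        auto_id += 1
        while f"{prefix}{auto_id}" in node_ids:
            auto_id += 1
        return f"{prefix}{auto_id}"

    def geometry(element: etree._Element) -> tuple[float, float, float, float]:
        graphics = element.find(_q("Graphics"))
        if graphics is None:
            raise ParseError(
                f"{etree.QName(element).localname} without Graphics "
                f"(line {element.sourceline})"
            )
        try:
            return (
                float(graphics.get("CenterX")),
                float(graphics.get("CenterY")),
                float(graphics.get("Width")),
                float(graphics.get("Height")),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"bad Graphics geometry at line {graphics.sourceline}"
            ) from exc

    for element in root.iter(_q("DataNode")):
        x, y, w, h = geometry(element)
        node_id = element.get("GraphId") or fresh_id("n")
        attributes: dict[str, str] = {}
        if element.get("Type"):
            attributes["type"] = element.get("Type")
        xref = element.find(_q("Xref"))
        if xref is not None:
            if xref.get("Database"):
                attributes["xref_database"] = xref.get("Database")
            if xref.get("ID"):
                attributes["xref_id"] = xref.get("ID")
        nodes.append(
            Node(node_id, element.get("TextLabel", ""), NodeKind.DATA,
                 x, y, w, h, attributes)
        )
        node_ids.add(node_id)

    for tag, default_label in (("Label", ""), ("Shape", "")):
        for element in root.iter(_q(tag)):
            x, y, w, h = geometry(element)
            node_id = element.get("GraphId") or fresh_id("deco")
            label = element.get("TextLabel") or element.get("ShapeType") or default_label
            nodes.append(Node(node_id, label, NodeKind.DECORATION, x, y, w, h))
            node_ids.add(node_id)

    if not nodes:
        raise ParseError("GPML document contains no nodes")

    edges: list[Edge] = []
    for tag in ("Interaction", "GraphicalLine"):
        for element in root.iter(_q(tag)):
            points = element.findall(f"{_q('Graphics')}/{_q('Point')}")
            refs = [p.get("GraphRef") for p in points]
            if len(refs) < 2 or refs[0] is None or refs[-1] is None:
                logger.warning(
                    "%s at line %s has no resolvable endpoints; dropped",
                    tag, element.sourceline,
                )
                continue
            source, target = refs[0], refs[-1]
            if source not in node_ids or target not in node_ids:
                logger.warning(
                    "%s %s->%s references unknown GraphId; dropped",
                    tag, source, target,
                )
                continue
            edges.append(Edge(source, target))

    name = root.get("Name", "pathway")
    return normalized(NetworkMap(name, nodes, edges))


def write_gpml(network: NetworkMap) -> str:
    """Serialize a :class:`NetworkMap` to GPML 2013a text.

    Round-trip guarantee: ``read_gpml(write_gpml(m))`` reproduces node and
    edge counts, labels, kinds and center coordinates exactly, provided the
    map's bounding box already starts at (0, 0).
    """
    root = etree.Element(_q("Pathway"), nsmap={None: GPML_NS})
    root.set("Name", network.name)
    for node in network.nodes:
        tag = "DataNode" if node.is_data_node else "Label"
        element = etree.SubElement(root, _q(tag))
        element.set("TextLabel", node.label)
        element.set("GraphId", node.node_id)
        graphics = etree.SubElement(element, _q("Graphics"))
        graphics.set("CenterX", _num(node.x))
        graphics.set("CenterY", _num(node.y))
        graphics.set("Width", _num(node.width))
        graphics.set("Height", _num(node.height))
        if node.is_data_node:
            xref = etree.SubElement(element, _q("Xref"))
            xref.set("Database", node.attributes.get("xref_database", ""))
            xref.set("ID", node.attributes.get("xref_id", ""))
    for edge in network.edges:
        interaction = etree.SubElement(root, _q("Interaction"))
        graphics = etree.SubElement(interaction, _q("Graphics"))
        for ref in (edge.source, edge.target):
            point = etree.SubElement(graphics, _q("Point"))
            point.set("GraphRef", ref)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _num(x: float) -> str:
    return f"{x:g}"


# ---------------------------------------------------------------------------
# SIF / GraphML
# ---------------------------------------------------------------------------

def _circle_layout(names: list[str], width: float = 80.0, height: float = 30.0) -> list[Node]:
    """Deterministic placement on a circle, radius proportional to node count."""
    n = len(names)
    radius = max(60.0, 25.0 * n)
    nodes = []
    for i, name in enumerate(names):
        angle = 2 * math.pi * i / n if n > 1 else 0.0
        x = radius + radius * math.cos(angle)
        y = radius + radius * math.sin(angle)
        nodes.append(Node(name, name, NodeKind.DATA, x, y, width, height))
    return nodes


def read_sif(stream: str, name: str = "network") -> NetworkMap:
    """Parse SIF (``source relation target [target ...]``; bare node lines
    introduce isolated nodes).  SIF carries no geometry, so nodes are laid
    out on a circle in order of first appearance."""
    order: list[str] = []
    seen: set[str] = set()
    pairs: list[tuple[str, str]] = []

    def add(node_name: str) -> None:
        if node_name not in seen:
            seen.add(node_name)
            order.append(node_name)

    for lineno, raw in enumerate(stream.splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if len(tokens) == 1:
            add(tokens[0])
        elif len(tokens) == 2:
            raise ParseError(
                f"SIF line {lineno}: got a relation with no target ({raw.strip()!r})"
            )
        else:
            source, _relation, *targets = tokens
            add(source)
            for target in targets:
                add(target)
                pairs.append((source, target))
    if not order:
        raise ParseError("SIF input contains no nodes")
    nodes = _circle_layout(order)
    edges = [Edge(s, t) for s, t in pairs]
    return normalized(NetworkMap(name, nodes, edges))


def read_graphml(stream: str, name: str = "network") -> NetworkMap:
    """Parse GraphML via networkx.

    If every node carries numeric ``x``/``y`` attributes those are used as
    centers; otherwise nodes get the deterministic circular layout.
    """
    try:
        graph = nx.parse_graphml(stream)
    except Exception as exc:  # networkx raises several lxml/KeyError flavours
        raise ParseError(f"malformed GraphML: {exc}") from exc
    if graph.number_of_nodes() == 0:
        raise ParseError("GraphML input contains no nodes")
    names = [str(n) for n in graph.nodes()]
    data = {str(n): d for n, d in graph.nodes(data=True)}

    def position(attrs: dict) -> tuple[float, float] | None:
        try:
            return float(attrs["x"]), float(attrs["y"])
        except (KeyError, TypeError, ValueError):
            return None

    positions = [position(data[n]) for n in names]
    if all(p is not None for p in positions):
        nodes = [
            Node(n, str(data[n].get("label", n)), NodeKind.DATA, p[0], p[1], 80.0, 30.0)
            for n, p in zip(names, positions)
        ]
    else:
        nodes = _circle_layout(names)
        nodes = [
            Node(n.node_id, str(data[n.node_id].get("label", n.node_id)),
                 n.kind, n.x, n.y, n.width, n.height)
            for n in nodes
        ]
    edges = [Edge(str(u), str(v)) for u, v in graph.edges()]
    return normalized(NetworkMap(name, nodes, edges))


def read_simple_network(stream: str, format: Literal["SIF", "GraphML"], name: str = "network") -> NetworkMap:
    """Read a geometry-free network in SIF or GraphML form."""
    if format == "SIF":
        return read_sif(stream, name=name)
    if format == "GraphML":
        return read_graphml(stream, name=name)
    raise ValueError(f"unknown network format {format!r}")


def read_network(path: str, format: str = "auto") -> NetworkMap:
    """Read a map/network file, sniffing the format when ``auto``.

    Sniffing: extension first (.gpml/.sif/.graphml/.xml), then — for XML —
    the root element's namespace.
    """
    with open(path, encoding="utf-8") as handle:
        text = handle.read()
    fmt = format
    if fmt == "auto":
        lowered = path.lower()
        if lowered.endswith(".gpml"):
            fmt = "gpml"
        elif lowered.endswith(".sif"):
            fmt = "sif"
        elif lowered.endswith(".graphml"):
            fmt = "graphml"
        elif text.lstrip().startswith("<"):
            fmt = "gpml" if GPML_NS in text else "graphml"
        else:
            fmt = "sif"
    name = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    if fmt == "gpml":
        return read_gpml(text)
    if fmt == "sif":
        return read_sif(text, name=name)
    if fmt == "graphml":
        return read_graphml(text, name=name)
    raise ValueError(f"unknown network format {format!r}")
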