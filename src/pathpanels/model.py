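"""Core domain containers shared by every stage of the pipeline.

The central object is a :class:`NetworkMap`: a named set of nodes with canvas
geometry (origin top-left, y grows downward, matching both GPML and SVG) plus
undirected edges between them.  Nodes are either *data nodes* — biological
entities (genes, proteins, metabolites) that measurement data can bind to —
or *decorations* — labels and shapes that are drawn but never carry data.

Measurement input is a :class:`DataTable`: one identifier column followed by
ordered numeric columns, with missing cells represented as ``None``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class PathPanelsError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PathPanelsError):
    """Malformed input file (network, map or data table)."""


class BindingError(PathPanelsError):
    """Data table cannot be bound to the map as requested."""


class ConfigError(PathPanelsError):
    """Invalid configuration (bad option values or inconsistent settings)."""


class NodeKind(enum.Enum):
    DATA = "data_node"
    DECORATION = "decoration"


@dataclass(frozen=True)
class Node:
    """A positioned map element.

    ``x``/``y`` give the node *center* in canvas units; ``width``/``height``
    must be positive.  ``attributes`` holds free-form string metadata such as
    cross-references (``xref_database``/``xref_id``) or a Cytoscape-style
    ``shared name``; the binding stage can match table identifiers against
    any attribute, the node label being the default key.
    """

    node_id: str
    label: str
    kind: NodeKind
    x: float
    y: float
    width: float
    height: float
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"node {self.node_id!r}: width and height must be positive "
                f"(got {self.width} x {self.height})"
            )

    @property
    def is_data_node(self) -> bool:
        return self.kind is NodeKind.DATA


@dataclass(frozen=True)
class Edge:
    """An undirected connection between two nodes, by node id."""

    source: str
    target: str


@dataclass
class NetworkMap:
    """A pathway map or plain network: the template replicated per sample."""

    name: str
    nodes: list[Node]
    edges: list[Edge]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("a map must contain at least one node")
        seen: set[str] = set()
        for node in self.nodes:
            if node.node_id in seen:
                raise ValueError(f"duplicate node id {node.node_id!r}")
            seen.add(node.node_id)
        for edge in self.edges:
            for endpoint in (edge.source, edge.target):
                if endpoint not in seen:
                    raise ValueError(
                        f"edge {edge.source!r}->{edge.target!r}: "
                        f"unknown endpoint {endpoint!r}"
                    )

    @property
    def node_by_id(self) -> dict[str, Node]:
        return {n.node_id: n for n in self.nodes}

    @property
    def data_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.is_data_node]

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) over all node rectangles."""
        xs0 = [n.x - n.width / 2 for n in self.nodes]
        ys0 = [n.y - n.height / 2 for n in self.nodes]
        xs1 = [n.x + n.width / 2 for n in self.nodes]
        ys1 = [n.y + n.height / 2 for n in self.nodes]
        return min(xs0), min(ys0), max(xs1), max(ys1)

    @property
    def extent(self) -> tuple[float, float]:
        """Width and height of the bounding box."""
        x0, y0, x1, y1 = self.bounding_box()
        return x1 - x0, y1 - y0


def normalized(network: NetworkMap) -> NetworkMap:
    """Translate all nodes uniformly so the bounding box starts at (0, 0)."""
    x0, y0, _, _ = network.bounding_box()
    if x0 == 0 and y0 == 0:
        return network
    moved = [
        Node(n.node_id, n.label, n.kind, n.x - x0, n.y - y0,
             n.width, n.height, dict(n.attributes))
        for n in network.nodes
    ]
    return NetworkMap(network.name, moved, list(network.edges))


@dataclass
class DataTable:
    """A parsed delimited measurement table.

    ``columns`` is the full ordered header, including the identifier column.
    Each row pairs an identifier with one optional float per non-identifier
    column (missing or non-numeric cells are ``None``).  Rows remember their
    1-based source line number (header = line 1) for error messages.
    """

    id_column: str
    columns: list[str]
    rows: list[tuple[str, tuple[float | None, ...]]]
    line_numbers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("column names must be unique")
        if self.id_column not in self.columns:
            raise ValueError(f"identifier column {self.id_column!r} not in header")
        n_values = len(self.columns) - 1
        for identifier, values in self.rows:
            if not identifier:
                raise ValueError("identifier cells must be non-empty")
            if len(values) != n_values:
                raise ValueError(
                    f"row {identifier!r}: expected {n_values} value cells, "
                    f"got {len(values)}"
                )
        if not self.line_numbers:
            self.line_numbers = [i + 2 for i in range(len(self.rows))]

    @property
    def value_columns(self) -> list[str]:
        """All non-identifier columns, in header order."""
        return [c for c in self.columns if c != self.id_column]

    def cell(self, row_index: int, column: str) -> float | None:
        idx = self.value_columns.index(column)
        return self.rows[row_index][1][idx]

    @property
    def identifiers(self) -> list[str]:
        return [identifier for identifier, _ in self.rows]


def finite_or_none(value: float | None) -> float | None:
    """Non-finite measurements are indistinguishable from missing ones."""
    if value is None or not math.isfinite(value):
        return None
    return value
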