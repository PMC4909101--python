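"""Synthetic pathway maps and matching measurement tables.

Every pipeline stage is testable without downloads: :func:`make_pathway`
builds a map (and its GPML text) with labelled gene nodes on a grid plus
optional decorations, and :func:`make_measurements` builds a matching
delimited table of per-sample values and p-values.

The defaults emulate a time-course expression experiment of five samples
(0, 2, 12, 24 and 72 h) with per-sample Bonferroni-style p-values, a
realistic shape for overlaying a treatment time series on a metabolic
pathway such as the glycolysis/TCA cycle.  Values are zero-mean normal
(log2-fold-change-like); a chosen fraction of rows per sample gets a
clearly significant p-value (uniform on [0, 0.025]) and the rest a clearly
non-significant one (uniform on (0.05, 1]).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .formats import parse_delimited_table, write_gpml
from .model import DataTable, Edge, NetworkMap, Node, NodeKind

#: p-values are generated relative to this reference threshold.
CUTOFF_REF = 0.05

_NODE_W, _NODE_H = 80.0, 30.0
_GRID_GAP = 40.0

#: Default sample names: a five-point treatment time course.
DEFAULT_SERIES_NAMES = ("0h", "2h", "12h", "24h", "72h")


@dataclass(frozen=True)
class FixtureParams:
    """Knobs for the synthetic map + table pair.

    ``frac_unmatched`` rows get novel identifiers absent from the map;
    ``frac_significant`` of rows per sample receive a p-value below
    ``CUTOFF_REF``; ``value_sd`` is the standard deviation of the
    zero-mean normal values.
    """

    n_nodes: int = 20
    n_edges: int = 24
    n_decorations: int = 2
    k_series: int = 5
    with_p: bool = True
    frac_significant: float = 0.4
    frac_unmatched: float = 0.1
    value_sd: float = 1.0
    seed: int = 0
    series_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.k_series < 1:
            raise ValueError("n_nodes and k_series must be positive")
        if self.n_edges < 0 or self.n_decorations < 0:
            raise ValueError("n_edges and n_decorations must be >= 0")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_edges > max_edges:
            raise ValueError(
                f"n_edges={self.n_edges} infeasible for {self.n_nodes} nodes "
                f"(max {max_edges})"
            )
        for name, frac in (("frac_significant", self.frac_significant),
                           ("frac_unmatched", self.frac_unmatched)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.value_sd <= 0:
            raise ValueError("value_sd must be positive")

    def resolved_series_names(self) -> tuple[str, ...]:
        if self.series_names is not None:
            if len(self.series_names) != self.k_series:
                raise ValueError("series_names length must equal k_series")
            return self.series_names
        if self.k_series == len(DEFAULT_SERIES_NAMES):
            return DEFAULT_SERIES_NAMES
        return tuple(f"S{i + 1}" for i in range(self.k_series))


def make_pathway(params: FixtureParams) -> tuple[NetworkMap, str]:
    """Build a synthetic pathway map and its GPML serialization.

    Data nodes are labelled ``G1..Gn`` on a deterministic grid whose
    bounding box starts at (0, 0); edges are distinct seeded random pairs;
    decorations are Label elements below the grid.  The GPML text
    re-parses to an equal map.
    """
    rng = np.random.default_rng(params.seed)
    n_cols = max(1, math.ceil(math.sqrt(params.n_nodes)))
    nodes: list[Node] = []
    for i in range(params.n_nodes):
        row, col = divmod(i, n_cols)
        nodes.append(Node(
            node_id=f"n{i + 1}",
            label=f"G{i + 1}",
            kind=NodeKind.DATA,
            x=_NODE_W / 2 + col * (_NODE_W + _GRID_GAP),
            y=_NODE_H / 2 + row * (_NODE_H + _GRID_GAP),
            width=_NODE_W,
            height=_NODE_H,
            attributes={"xref_database": "Ensembl", "xref_id": f"FIX{i + 1:04d}"},
        ))
    n_rows = math.ceil(params.n_nodes / n_cols)
    deco_y = _NODE_H / 2 + n_rows * (_NODE_H + _GRID_GAP)
    for j in range(params.n_decorations):
        nodes.append(Node(
            node_id=f"deco{j + 1}",
            label=f"Note {j + 1}",
            kind=NodeKind.DECORATION,
            x=60.0 + j * 160.0,
            y=deco_y,
            width=120.0,
            height=20.0,
        ))
    pairs = list(itertools.combinations(range(params.n_nodes), 2))
    edges: list[Edge] = []
    if params.n_edges and pairs:
        chosen = rng.choice(len(pairs), size=params.n_edges, replace=False)
        edges = [Edge(f"n{pairs[k][0] + 1}", f"n{pairs[k][1] + 1}")
                 for k in sorted(int(c) for c in chosen)]
    network = NetworkMap("synthetic-pathway", nodes, edges)
    return network, write_gpml(network)


def make_measurements(
    network: NetworkMap,
    params: FixtureParams,
) -> tuple[DataTable, str]:
    """Build a measurement table matching a map's data nodes.

    One row per data node, except that a seeded ``frac_unmatched`` subset
    gets novel identifiers (``U1..``) that match nothing.  Header is the
    identifier column followed by value (and, with p-values, value/p)
    columns in sample order.  Same seed, same bytes.
    """
    data_nodes = network.data_nodes
    if not data_nodes:
        raise ValueError("map has no data nodes to measure")
    rng = np.random.default_rng(params.seed + 1)
    names = params.resolved_series_names()
    n = len(data_nodes)

    identifiers = [node.label for node in data_nodes]
    n_unmatched = round(params.frac_unmatched * n)
    if n_unmatched:
        swap = rng.choice(n, size=n_unmatched, replace=False)
        for j, row in enumerate(sorted(int(s) for s in swap)):
            identifiers[row] = f"U{j + 1}"

    header = ["id"]
    for name in names:
        header.append(name)
        if params.with_p:
            header.append(f"p_{name}")

    lines = [",".join(header)]
    values = rng.normal(0.0, params.value_sd, size=(n, len(names)))
    significant = rng.random(size=(n, len(names))) < params.frac_significant
    p_low = rng.uniform(0.0, CUTOFF_REF / 2, size=(n, len(names)))
    p_high = rng.uniform(CUTOFF_REF, 1.0, size=(n, len(names)))
    for i, identifier in enumerate(identifiers):
        cells = [identifier]
        for s in range(len(names)):
            cells.append(f"{values[i, s]:.4f}")
            if params.with_p:
                p = p_low[i, s] if significant[i, s] else p_high[i, s]
                cells.append(f"{p:.6f}")
        lines.append(",".join(cells))
    csv_text = "\n".join(lines) + "\n"
    table = parse_delimited_table(csv_text, "comma", source="<fixture>")
    return table, csv_text


def use_case_fixture(seed: int = 0) -> tuple[NetworkMap, DataTable]:
    """The default end-to-end fixture: five-sample time course with
    p-values over a ~20-node pathway."""
    params = FixtureParams(seed=seed)
    network, _ = make_pathway(params)
    table, _ = make_measurements(network, params)
    return network, table
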