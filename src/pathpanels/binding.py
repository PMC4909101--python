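"""Detect sample structure in a measurement table and bind it to map nodes.

The auto-binding rule follows column order: the identifier column comes
first; if the remaining column count is even, consecutive pairs are read as
(value, p-value) series; if odd, every remaining column becomes a
value-only series.  Matching between table identifiers and nodes is exact
and case-sensitive on a chosen node attribute (the label by default) — no
fuzzy matching and no identifier-system translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import (
    BindingError,
    DataTable,
    NetworkMap,
    Node,
    finite_or_none,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleSeries:
    """One sample/experiment: a value column with an optional p-value column."""

    name: str
    value_column: str
    p_column: str | None = None

    def __post_init__(self) -> None:
        if self.p_column is not None and self.p_column == self.value_column:
            raise ValueError(
                f"series {self.name!r}: p column must differ from value column"
            )


@dataclass(frozen=True)
class BindingSpec:
    """How table columns map onto samples and which node attribute is the key.

    ``match_attribute`` names the node attribute compared against the table
    identifier column; the special value ``"label"`` uses the node label.
    """

    id_column: str
    series: tuple[SampleSeries, ...]
    match_attribute: str = "label"

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("binding spec needs at least one series")
        used = [self.id_column]
        for s in self.series:
            used.append(s.value_column)
            if s.p_column:
                used.append(s.p_column)
        if len(set(used)) != len(used):
            raise ValueError("id/value/p columns must all be distinct")

    def validate_against(self, table: DataTable) -> None:
        if self.id_column != table.id_column:
            raise BindingError(
                f"spec identifier column {self.id_column!r} does not match "
                f"table identifier column {table.id_column!r}"
            )
        available = set(table.value_columns)
        for s in self.series:
            for column in filter(None, (s.value_column, s.p_column)):
                if column not in available:
                    raise BindingError(
                        f"series {s.name!r}: column {column!r} not in table"
                    )

    @property
    def all_have_p(self) -> bool:
        return all(s.p_column is not None for s in self.series)


@dataclass(frozen=True)
class NodeDatum:
    """A bound measurement: signed value (e.g. log2 fold change) plus
    optional p-value in [0, 1]."""

    value: float
    p: float | None = None

    def __post_init__(self) -> None:
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class BindingResult:
    """Outcome of matching a table against a map.

    ``series_data`` maps series name -> {node_id -> NodeDatum}; a node
    appears in a series' map only when its value cell is present, so absence
    from the map means "no data" for that sample.  Conservation invariant:
    ``len(matched_node_ids) + len(unmatched_identifiers)`` equals the number
    of distinct table identifiers.
    """

    series_data: dict[str, dict[str, NodeDatum]]
    matched_node_ids: set[str]
    unmatched_identifiers: list[str]
    discarded_duplicates: int = 0
    spec: BindingSpec | None = field(default=None, compare=False)


def auto_bind(table: DataTable) -> BindingSpec:
    """Derive a :class:`BindingSpec` from column order alone.

    The first column holds identifiers.  An even number of remaining
    columns pairs up as (value, p) per sample; an odd count falls back to
    one value-only series per column (pairing would have to guess which
    column lacks its p-value partner).  Series are named after their value
    column, in left-to-right order.
    """
    remaining = table.value_columns
    if not remaining:
        raise BindingError("nothing to bind: table has no columns besides the identifier")
    series: list[SampleSeries] = []
    if len(remaining) % 2 == 0:
        for value_col, p_col in zip(remaining[0::2], remaining[1::2]):
            series.append(SampleSeries(name=value_col, value_column=value_col, p_column=p_col))
    else:
        for value_col in remaining:
            series.append(SampleSeries(name=value_col, value_column=value_col))
    return BindingSpec(id_column=table.id_column, series=tuple(series))


def _node_key(node: Node, match_attribute: str) -> str | None:
    if match_attribute == "label":
        return node.label or None
    return node.attributes.get(match_attribute)


def match_identifiers(
    network: NetworkMap,
    table: DataTable,
    spec: BindingSpec,
    allow_duplicates: bool = False,
) -> BindingResult:
    """Match table identifiers to data nodes and collect per-series data.

    Matching is exact and case-sensitive.  Decoration nodes never match.
    Duplicate identifiers in the table are an error unless
    ``allow_duplicates`` is set, in which case the first occurrence wins
    and a warning counts the discards.
    """
    spec.validate_against(table)

    key_to_nodes: dict[str, list[str]] = {}
    for node in network.data_nodes:
        key = _node_key(node, spec.match_attribute)
        if key is not None:
            key_to_nodes.setdefault(key, []).append(node.node_id)

    seen: dict[str, int] = {}
    discarded = 0
    kept_rows: list[int] = []
    for i, identifier in enumerate(table.identifiers):
        if identifier in seen:
            if not allow_duplicates:
                raise BindingError(
                    f"duplicate identifier {identifier!r} "
                    f"(line {table.line_numbers[i]})"
                )
            discarded += 1
            continue
        seen[identifier] = i
        kept_rows.append(i)
    if discarded:
        logger.warning("discarded %d duplicate table rows (first occurrence wins)", discarded)

    series_data: dict[str, dict[str, NodeDatum]] = {s.name: {} for s in spec.series}
    matched: set[str] = set()
    unmatched: list[str] = []
    for i in kept_rows:
        identifier = table.identifiers[i]
        node_ids = key_to_nodes.get(identifier)
        if not node_ids:
            unmatched.append(identifier)
            continue
        matched.update(node_ids)
        for s in spec.series:
            value = finite_or_none(table.cell(i, s.value_column))
            if value is None:
                continue  # missing value cell => no-data for this series
            p = finite_or_none(table.cell(i, s.p_column)) if s.p_column else None
            if p is not None and not 0.0 <= p <= 1.0:
                raise BindingError(
                    f"series {s.name!r}, identifier {identifier!r}: "
                    f"p-value {p} outside [0, 1]"
                )
            datum = NodeDatum(value=value, p=p)
            for node_id in node_ids:
                series_data[s.name][node_id] = datum
    return BindingResult(
        series_data=series_data,
        matched_node_ids=matched,
        unmatched_identifiers=unmatched,
        discarded_duplicates=discarded,
        spec=spec,
    )
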