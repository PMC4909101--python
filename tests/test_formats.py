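"""Readers/writers: separator sniffing, delimited tables, GPML, SIF, GraphML."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pathpanels import (
    FixtureParams,
    NodeKind,
    ParseError,
    detect_separator,
    make_pathway,
    parse_delimited_table,
    read_gpml,
    read_graphml,
    read_sif,
    write_gpml,
)

GPML_TWO_NODES = """<?xml version="1.0" encoding="UTF-8"?>
<Pathway xmlns="http://pathvisio.org/GPML/2013a" Name="demo">
  <DataNode TextLabel="PFK1" GraphId="n1">
    <Graphics CenterX="100" CenterY="50" Width="80" Height="30"/>
    <Xref Database="Ensembl" ID="AT4G26270"/>
  </DataNode>
  <DataNode TextLabel="PK" GraphId="n2">
    <Graphics CenterX="260" CenterY="50" Width="80" Height="30"/>
  </DataNode>
  <Interaction>
    <Graphics>
      <Point X="140" Y="50" GraphRef="n1"/>
      <Point X="220" Y="50" GraphRef="n2"/>
    </Graphics>
  </Interaction>
</Pathway>
"""


class TestDetectSeparator:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("a,b,c\nd,e,f", "comma"),
            ("a\tb\nc\td", "tab"),
            ("a;b;c\nd;e;f", "semicolon"),
            ("a b c\nd e f", "whitespace"),
            # more columns wins over precedence
            ("a,b c,d\ne,f g,h", "comma"),
        ],
    )
    def test_unambiguous_inputs(self, text, expected):
        assert detect_separator(text) == expected

    def test_tab_precedence_on_tie(self):
        # both tab and comma give a consistent 2 columns
        assert detect_separator("a\tb,c\td\ne\tf,g\th") == "tab"

    @pytest.mark.parametrize("text", ["abc\ndef", "", "   \n  "])
    def test_undetectable(self, text):
        with pytest.raises(ParseError, match="undetectable separator"):
            detect_separator(text)


class TestDelimitedTable:
    def test_basic_comma_table(self):
        table = parse_delimited_table("id,fc,p\nG1,2.0,0.01", "comma")
        assert table.columns == ["id", "fc", "p"]
        assert table.rows == [("G1", (2.0, 0.01))]

    def test_whitespace_runs_collapse(self):
        table = parse_delimited_table("id  fc\tp\nG1  2.0\t0.01", "whitespace")
        assert table.rows == [("G1", (2.0, 0.01))]

    def test_ragged_row_names_line(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_delimited_table("id,fc,p\nG1,2.0", "comma")

    @pytest.mark.parametrize("text,message", [
        ("", "empty"),
        ("id,fc,p\n", "header-only"),
    ])
    def test_degenerate_files(self, text, message):
        with pytest.raises(ParseError, match=message):
            parse_delimited_table(text, "comma")

    @pytest.mark.parametrize("cell", ["", "NA", "inf", "nan"])
    def test_missing_and_nonnumeric_cells(self, cell):
        table = parse_delimited_table(f"id,fc\nG1,{cell}", "comma")
        assert table.rows[0][1] == (None,)

    def test_named_id_column(self):
        table = parse_delimited_table("fc,name,p\n2.0,G1,0.01", "comma",
                                      id_column="name")
        assert table.id_column == "name"
        assert table.rows == [("G1", (2.0, 0.01))]
        assert table.value_columns == ["fc", "p"]

    @given(st.integers(0, 10_000), st.integers(2, 6), st.integers(1, 8))
    def test_separator_agnostic(self, seed, n_cols, n_rows):
        """The same logical table parses identically under all four separators."""
        import random

        rng = random.Random(seed)
        header = [f"c{i}" for i in range(n_cols)]
        rows = [
            [f"r{j}"] + [f"{rng.uniform(-5, 5):.3f}" for _ in range(n_cols - 1)]
            for j in range(n_rows)
        ]
        parsed = []
        for sep_name, sep in [("comma", ","), ("semicolon", ";"),
                              ("tab", "\t"), ("whitespace", " ")]:
            text = "\n".join(sep.join(cells) for cells in [header] + rows)
            parsed.append(parse_delimited_table(text, sep_name))
        assert all(t == parsed[0] for t in parsed[1:])


class TestGPML:
    def test_datanodes_and_interaction(self):
        network = read_gpml(GPML_TWO_NODES)
        assert len(network.data_nodes) == 2
        assert len(network.edges) == 1
        pfk = network.node_by_id["n1"]
        assert pfk.label == "PFK1"
        assert pfk.attributes["xref_database"] == "Ensembl"
        assert pfk.attributes["xref_id"] == "AT4G26270"

    def test_label_becomes_decoration(self):
        text = GPML_TWO_NODES.replace(
            "</Pathway>",
            '<Label TextLabel="glycolysis" GraphId="l1">'
            '<Graphics CenterX="50" CenterY="200" Width="100" Height="20"/>'
            "</Label></Pathway>",
        )
        network = read_gpml(text)
        kinds = [n.kind for n in network.nodes]
        assert kinds.count(NodeKind.DATA) == 2
        assert kinds.count(NodeKind.DECORATION) == 1

    def test_unknown_graphref_dropped_with_warning(self, caplog):
        text = GPML_TWO_NODES.replace('GraphRef="n2"', 'GraphRef="missing"')
        with caplog.at_level("WARNING"):
            network = read_gpml(text)
        assert len(network.edges) == 0
        assert any("unknown GraphId" in r.message for r in caplog.records)

    def test_coordinates_normalized_to_origin(self):
        network = read_gpml(GPML_TWO_NODES)
        x0, y0, _, _ = network.bounding_box()
        assert (x0, y0) == (0.0, 0.0)

    @pytest.mark.parametrize("mangle,message", [
        (lambda t: "not xml at all", "well-formed"),
        (lambda t: t.replace("http://pathvisio.org/GPML/2013a", "urn:other"),
         "GPML namespace"),
        (lambda t: t.replace(
            '<Graphics CenterX="100" CenterY="50" Width="80" Height="30"/>', ""),
         "without Graphics"),
    ])
    def test_rejects_bad_input(self, mangle, message):
        with pytest.raises(ParseError, match=message):
            read_gpml(mangle(GPML_TWO_NODES))

    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_write_read_round_trip(self, seed):
        """Serialization preserves counts, labels, kinds and coordinates."""
        network, gpml_text = make_pathway(FixtureParams(seed=seed, n_decorations=2))
        reread = read_gpml(gpml_text)
        assert len(reread.nodes) == len(network.nodes)
        assert len(reread.edges) == len(network.edges)
        original = {n.node_id: n for n in network.nodes}
        for node in reread.nodes:
            ref = original[node.node_id]
            assert (node.label, node.kind) == (ref.label, ref.kind)
            assert (node.x, node.y) == (ref.x, ref.y)
            assert (node.width, node.height) == (ref.width, ref.height)
        assert {(e.source, e.target) for e in reread.edges} == \
            {(e.source, e.target) for e in network.edges}


class TestSimpleNetworks:
    def test_sif_nodes_and_edges(self):
        network = read_sif("A pp B\nB pp C")
        assert {n.node_id for n in network.nodes} == {"A", "B", "C"}
        assert len(network.edges) == 2
        assert all(n.kind is NodeKind.DATA for n in network.nodes)

    def test_sif_isolated_node(self):
        network = read_sif("A")
        assert len(network.nodes) == 1
        assert network.edges == []

    def test_sif_multiple_targets(self):
        network = read_sif("A pp B C D")
        assert len(network.edges) == 3

    def test_sif_relation_without_target_rejected(self):
        with pytest.raises(ParseError, match="line 1"):
            read_sif("A pp")

    def test_sif_layout_deterministic(self):
        first = read_sif("A pp B\nB pp C")
        second = read_sif("A pp B\nB pp C")
        assert [(n.x, n.y) for n in first.nodes] == \
            [(n.x, n.y) for n in second.nodes]

    def test_graphml_without_positions_gets_circle(self):
        text = (
            '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">'
            '<graph edgedefault="undirected">'
            '<node id="A"/><node id="B"/><edge source="A" target="B"/>'
            "</graph></graphml>"
        )
        network = read_graphml(text)
        assert {n.node_id for n in network.nodes} == {"A", "B"}
        assert len(network.edges) == 1
        again = read_graphml(text)
        assert [(n.x, n.y) for n in network.nodes] == \
            [(n.x, n.y) for n in again.nodes]

    def test_graphml_malformed_rejected(self):
        with pytest.raises(ParseError):
            read_graphml("<graphml><unclosed")

    @pytest.mark.parametrize("seed", range(5))
    def test_edges_always_resolve(self, seed):
        """Every edge endpoint in a returned map is a real node."""
        network, _ = make_pathway(FixtureParams(seed=seed, n_nodes=10, n_edges=15))
        ids = {n.node_id for n in network.nodes}
        for edge in network.edges:
            assert edge.source in ids and edge.target in ids


def test_gpml_text_is_stable(triangle_map):
    assert write_gpml(triangle_map) == write_gpml(triangle_map)
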