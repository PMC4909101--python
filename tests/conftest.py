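import pytest
from hypothesis import HealthCheck, settings

from pathpanels import (
    Edge,
    NetworkMap,
    Node,
    NodeKind,
    parse_delimited_table,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_node(node_id, label=None, kind=NodeKind.DATA, x=50.0, y=50.0):
    return Node(node_id, label if label is not None else node_id, kind,
                x, y, 80.0, 30.0)


@pytest.fixture
def triangle_map():
    """Three gene nodes A-B-C with two edges, plus one decoration."""
    nodes = [
        make_node("a", "A", x=40.0, y=15.0),
        make_node("b", "B", x=160.0, y=15.0),
        make_node("c", "C", x=100.0, y=100.0),
        make_node("d1", "note", kind=NodeKind.DECORATION, x=100.0, y=160.0),
    ]
    edges = [Edge("a", "b"), Edge("b", "c")]
    return NetworkMap("triangle", nodes, edges)


@pytest.fixture
def small_table():
    """id + 2 (value, p) sample pairs; C has a missing value in sample t1."""
    text = (
        "id,t0,p_t0,t1,p_t1\n"
        "A,1.5,0.01,2.0,0.2\n"
        "B,-0.5,0.8,-2.0,0.001\n"
        "C,0.25,0.04,,0.5\n"
        "X,3.0,0.001,1.0,0.01\n"
    )
    return parse_delimited_table(text, "comma")
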