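import numpy as np
import pytest

from pcdsp import Dataset, PartiallyDirectedGraph, Variable, VariableTable


@pytest.fixture
def small_table():
    return VariableTable(
        [("A", "cardinal", 3), ("B", "ordinal", 8), ("C", "binary", 1)]
    )


@pytest.fixture
def gaussian_pair():
    """1000 rows of two independent standard normals."""
    rng = np.random.default_rng(42)
    table = VariableTable([("x", "cardinal", 1), ("y", "cardinal", 1)])
    return Dataset(rng.normal(size=(1000, 2)), table), table


@pytest.fixture
def collider_graph():
    """A -> C <- B with sepset(A, B) = {} recorded."""
    g = PartiallyDirectedGraph(["A", "B", "C"])
    g.add_edge("A", "C")
    g.add_edge("B", "C")
    g.set_sepset("A", "B", ())
    return g
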