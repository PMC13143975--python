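"""Container invariants and file round trips."""

import numpy as np
import pytest

from pcdsp import (
    Dataset,
    FormatError,
    PartiallyDirectedGraph,
    RunConfig,
    SchemaError,
    ValidationError,
    Variable,
    VariableTable,
    read_config,
    read_dataset,
    read_network,
    read_variable_table,
    write_dataset,
    write_network,
    write_run_log,
    write_variable_table,
)
from pcdsp.io import NETWORK_FORMATS


# ---------------------------------------------------------------------------
# variable table


def test_variable_table_parses_three_entries(tmp_path):
    p = tmp_path / "vars.csv"
    p.write_text("name,vtype,epoque\nA,cardinal,3\nB,ordinal,8\nC,binary,1\n")
    table = read_variable_table(p)
    assert table.names == ["A", "B", "C"]
    assert table.vtype_of("B") == "ordinal"
    assert table.epoque_of("C") == 1


@pytest.mark.parametrize(
    "body, exc, fragment",
    [
        ("name,vtype,epoque\nA,cardinal,3\nA,binary,1\n", ValidationError, "duplicate"),
        ("name,vtype,epoque\nA,cardinal,9\n", ValidationError, "epoque"),
        ("name,vtype,epoque\nA,cardinal,zero\n", FormatError, "integer"),
        ("name,vtype,epoque\nA,nominal,2\n", ValidationError, "vtype"),
        ("name,kind\nA,cardinal\n", FormatError, "header"),
        ("name,vtype,epoque\nbad name,cardinal,2\n", ValidationError, "name"),
    ],
)
def test_variable_table_rejects_invalid_files(tmp_path, body, exc, fragment):
    p = tmp_path / "vars.csv"
    p.write_text(body)
    with pytest.raises(exc, match=fragment):
        read_variable_table(p)


def test_variable_table_round_trip(tmp_path, small_table):
    p = tmp_path / "vars.csv"
    write_variable_table(small_table, p)
    assert read_variable_table(p) == small_table


# ---------------------------------------------------------------------------
# dataset


def test_read_dataset_marks_sentinel_missing(tmp_path, small_table):
    p = tmp_path / "d.csv"
    p.write_text("A,B,C\n1.5,2,0\nNA,1,1\n0.25,0,0\n-3.0,4,1\n")
    d = read_dataset(p, small_table)
    assert d.missing_mask().sum() == 1
    assert np.isnan(d.column("A")[1])
    assert d.n_missing_per_column() == {"A": 1, "B": 0, "C": 0}


def test_read_dataset_reorders_columns(tmp_path, small_table):
    p = tmp_path / "d.csv"
    p.write_text("C,A,B\n1,0.5,2\n0,1.5,3\n")
    d = read_dataset(p, small_table)
    assert d.columns == ["A", "B", "C"]
    assert d.column("A")[0] == 0.5


def test_read_dataset_rejects_schema_and_parse_errors(tmp_path, small_table):
    extra = tmp_path / "extra.csv"
    extra.write_text("A,B,C,D\n1,2,0,9\n")
    with pytest.raises(SchemaError, match="D"):
        read_dataset(extra, small_table)
    short = tmp_path / "short.csv"
    short.write_text("A,B\n1,2\n")
    with pytest.raises(SchemaError, match="C"):
        read_dataset(short, small_table)
    bad = tmp_path / "bad.csv"
    bad.write_text("A,B,C\n1,two,0\n")
    with pytest.raises(FormatError, match="two"):
        read_dataset(bad, small_table)


@pytest.mark.parametrize("sentinel", ["NA", "?"])
def test_dataset_round_trip_preserves_values_and_mask(tmp_path, small_table, sentinel):
    rng = np.random.default_rng(0)
    values = np.column_stack(
        [
            rng.normal(size=20),
            rng.integers(0, 5, 20).astype(float),
            rng.integers(0, 2, 20).astype(float),
        ]
    )
    values[rng.random(values.shape) < 0.2] = np.nan
    d = Dataset(values, small_table)
    p = tmp_path / "d.csv"
    write_dataset(d, p, missing_sentinel=sentinel)
    back = read_dataset(p, small_table, missing_sentinel=sentinel)
    assert np.array_equal(d.missing_mask(), back.missing_mask())
    assert np.allclose(d.values, back.values, equal_nan=True)


def test_dataset_rejects_degenerate_shapes(small_table):
    with pytest.raises(ValidationError):
        Dataset(np.zeros((0, 3)), small_table)
    with pytest.raises(ValidationError):
        Dataset(np.zeros((5, 1)), VariableTable([("A", "cardinal", 1)]))
    with pytest.raises(ValidationError, match="non-integer"):
        Dataset(
            np.array([[0.5, 1.5, 0.0]]), small_table
        )  # B is ordinal but fractional


# ---------------------------------------------------------------------------
# partially directed graphs


def test_graph_basic_invariants():
    g = PartiallyDirectedGraph(["A", "B", "C"])
    g.add_edge("A", "B", head="B", provenance="temporal")
    g.add_edge("B", "C")
    with pytest.raises(ValidationError, match="self-loop"):
        g.add_edge("A", "A")
    with pytest.raises(ValidationError, match="already present"):
        g.add_edge("B", "A")
    with pytest.raises(ValidationError, match="other way"):
        g.orient("B", "A", "meek")
    assert g.parents("B") == ["A"]
    assert g.undirected_neighbors("B") == ["C"]


def test_graph_validate_catches_cycles_and_time_violations(small_table):
    g = PartiallyDirectedGraph(["A", "B", "C"])
    g.add_edge("A", "B", head="B")
    g.add_edge("B", "C", head="C")
    g.add_edge("C", "A", head="A")
    with pytest.raises(ValidationError, match="cycle"):
        g.validate()

    h = PartiallyDirectedGraph(["A", "C"])
    h.add_edge("A", "C", head="C")  # A is epoque 3, C is epoque 1
    with pytest.raises(ValidationError, match="epoque"):
        h.validate(small_table)


def test_creates_cycle_detection():
    g = PartiallyDirectedGraph(["A", "B", "C"])
    g.add_edge("A", "B", head="B")
    g.add_edge("B", "C", head="C")
    g.add_edge("A", "C")
    assert g.creates_cycle("C", "A")
    assert not g.creates_cycle("A", "C")


# ---------------------------------------------------------------------------
# network writers


def _two_edge_graph():
    g = PartiallyDirectedGraph(["A", "B", "C"])
    g.add_edge("A", "B", head="B", provenance="temporal")
    g.add_edge("B", "C")
    return g


def test_edge_list_tsv_contents_and_round_trip(tmp_path):
    g = _two_edge_graph()
    p = tmp_path / "net.tsv"
    write_network(g, p, "edge_list_tsv", stability={frozenset(("A", "B")): 87.0})
    lines = p.read_text().splitlines()
    assert lines[0].split("\t") == [
        "source", "target", "orientation", "provenance", "stability",
    ]
    assert "A\tB\tdirected\ttemporal\t87.0" in lines
    # edge missing from the stability map gets an empty field
    assert "B\tC\tundirected\tnone\t" in lines
    assert read_network(p) == g


def test_sif_uses_causes_and_assoc_labels(tmp_path):
    p = tmp_path / "net.sif"
    write_network(_two_edge_graph(), p, "sif")
    text = p.read_text()
    assert "A\tcauses\tB" in text
    assert "B\tassoc\tC" in text


def test_graphml_stores_epoque_attribute(tmp_path, small_table):
    import xml.etree.ElementTree as ET

    p = tmp_path / "net.graphml"
    write_network(_two_edge_graph(), p, "graphml", table=small_table)
    ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
    root = ET.parse(p).getroot()
    epoques = {
        n.get("id"): d.text
        for n in root.iter("{http://graphml.graphdrawing.org/xmlns}node")
        for d in n
    }
    assert epoques == {"A": "3", "B": "8", "C": "1"}


def test_write_network_rejects_unknown_format_and_invalid_graphs(tmp_path):
    with pytest.raises(ValueError, match="unknown network format"):
        write_network(_two_edge_graph(), tmp_path / "x", "dot")
    cyc = PartiallyDirectedGraph(["A", "B"])
    cyc.add_edge("A", "B", head="B")
    cyc2 = PartiallyDirectedGraph(["A", "B", "C"])
    cyc2.add_edge("A", "B", head="B")
    cyc2.add_edge("B", "C", head="C")
    cyc2.add_edge("C", "A", head="A")
    with pytest.raises(ValidationError, match="cycle"):
        write_network(cyc2, tmp_path / "c.tsv", "edge_list_tsv")


@pytest.mark.parametrize("fmt", NETWORK_FORMATS)
def test_all_writers_accept_a_valid_graph(tmp_path, small_table, fmt):
    write_network(_two_edge_graph(), tmp_path / f"n.{fmt}", fmt, table=small_table)


# ---------------------------------------------------------------------------
# run configuration


def test_run_config_validation_and_log(tmp_path):
    with pytest.raises(ValidationError):
        RunConfig(alpha=1.5)
    with pytest.raises(ValidationError):
        RunConfig(bootstrap=0)
    cfg = RunConfig(target="T", seed=7)
    log = tmp_path / "run.json"
    write_run_log(cfg, log, n_edges=5)
    text = log.read_text()
    assert '"seed": 7' in text and '"n_edges": 5' in text


def test_read_config_rejects_unknown_keys(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("alpha: 0.05\nmax_q: 3\n")
    with pytest.raises(FormatError, match="max_q"):
        read_config(p)
    p.write_text("alpha: 0.01\ntarget: T\n")
    cfg = read_config(p)
    assert cfg.alpha == 0.01 and cfg.target == "T"
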