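"""Readers and writers: CSV data / variable tables, TSV / SIF / GraphML
networks, YAML run configuration, and JSON reports.

One delimited-text dialect throughout: comma-separated, UTF-8, header row
required, configurable missing-value sentinel (default ``"NA"``).
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    Dataset,
    FormatError,
    PartiallyDirectedGraph,
    SchemaError,
    ValidationError,
    Variable,
    VariableTable,
)

NETWORK_FORMATS = ("edge_list_tsv", "sif", "graphml")


def read_variable_table(path: str | Path) -> VariableTable:
    """Parse a variable table CSV with header columns name,vtype,epoque."""
    path = Path(path)
    entries = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "vtype", "epoque"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: header must contain columns name,vtype,epoque "
                f"(got {reader.fieldnames})"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                epoque = int(row["epoque"])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}:{lineno}: epoque {row.get('epoque')!r} is not an integer"
                ) from None
            try:
                entries.append(Variable(row["name"], row["vtype"], epoque))
            except ValidationError as err:
                raise ValidationError(f"{path}:{lineno}: {err}") from None
    return VariableTable(entries)


def write_variable_table(table: VariableTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_dataset(
    path: str | Path,
    table: VariableTable,
    missing_sentinel: str = "NA",
) -> Dataset:
    """Read a data CSV, reorder columns to the table, mark sentinel cells missing."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    extra = [c for c in cols if c not in table]
    absent = [n for n in table.names if n not in cols]
    if extra or absent:
        raise SchemaError(
            f"{path}: columns disagree with variable table "
            f"(unexpected: {extra or 'none'}; missing: {absent or 'none'})"
        )
    df = df[table.names]
    values = np.empty(df.shape, dtype=float)
    for j, name in enumerate(table.names):
        col = df[name].to_numpy()
        miss = col == missing_sentinel
        out = np.full(col.shape, np.nan)
        todo = ~miss
        try:
            out[todo] = col[todo].astype(float)
        except ValueError:
            bad = next(v for v in col[todo] if not _is_number(v))
            raise FormatError(
                f"{path}: column {name!r} has non-numeric, non-sentinel "
                f"cell {bad!r}"
            ) from None
        values[:, j] = out
    return Dataset(values, table)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_dataset(
    data: Dataset, path: str | Path, missing_sentinel: str = "NA"
) -> None:
    df = data.to_frame()
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(data.columns)
        vtypes = [data.table.vtype_of(c) for c in data.columns]
        for row in df.itertuples(index=False):
            out = []
            for val, vt in zip(row, vtypes):
                if pd.isna(val):
                    out.append(missing_sentinel)
                elif vt in ("binary", "ordinal"):
                    out.append(str(int(val)))
                else:
                    out.append(repr(float(val)))
            writer.writerow(out)


# ---------------------------------------------------------------------------
# networks


def write_network(
    g: PartiallyDirectedGraph,
    path: str | Path,
    fmt: str = "edge_list_tsv",
    stability: Optional[Mapping[frozenset, float]] = None,
    table: Optional[VariableTable] = None,
) -> None:
    """Write a learned network; re-validates acyclicity and epoque order."""
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; choose from {NETWORK_FORMATS}")
    g.validate(table)
    path = Path(path)
    if fmt == "edge_list_tsv":
        _write_edge_list_tsv(g, path, stability)
    elif fmt == "sif":
        _write_sif(g, path)
    else:
        _write_graphml(g, path, table, stability)


def _write_edge_list_tsv(g, path, stability) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\torientation\tprovenance\tstability\n")
        for e in g.edges():
            if e.directed:
                src, dst, orient = e.tail, e.head, "directed"
            else:
                src, dst, orient = e.u, e.v, "undirected"
            stab = ""
            if stability is not None:
                val = stability.get(frozenset((e.u, e.v)))
                if val is not None:
                    stab = f"{val:.1f}"
            fh.write(f"{src}\t{dst}\t{orient}\t{e.provenance}\t{stab}\n")


def read_network(path: str | Path) -> PartiallyDirectedGraph:
    """Read an edge_list_tsv network back into a graph (inverse of writing)."""
    path = Path(path)
    g = PartiallyDirectedGraph()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["source", "target", "orientation", "provenance"]:
            raise FormatError(f"{path}: unexpected edge-list header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 fields")
            src, dst, orient, prov = parts[:4]
            head = dst if orient == "directed" else None
            g.add_edge(src, dst, head=head, provenance=prov)
    return g


def _write_sif(g, path) -> None:
    # Cytoscape SIF: "node <interaction> node"; directed edges are "causes",
    # undirected ones "assoc".
    with path.open("w", encoding="utf-8") as fh:
        for e in g.edges():
            if e.directed:
                fh.write(f"{e.tail}\tcauses\t{e.head}\n")
            else:
                fh.write(f"{e.u}\tassoc\t{e.v}\n")
        connected = {n for e in g.edges() for n in (e.u, e.v)}
        for n in sorted(set(g.nodes) - connected):
            fh.write(f"{n}\n")


def _write_graphml(g, path, table, stability) -> None:
    graphml = ET.Element(
        "graphml", xmlns="http://graphml.graphdrawing.org/xmlns"
    )
    for key_id, target, name, typ in (
        ("epoque", "node", "epoque", "int"),
        ("provenance", "edge", "provenance", "string"),
        ("directed", "edge", "directed", "boolean"),
        ("stability", "edge", "stability", "double"),
    ):
        ET.SubElement(
            graphml, "key", id=key_id,
            attrib={"for": target, "attr.name": name, "attr.type": typ},
        )
    graph = ET.SubElement(graphml, "graph", id="G", edgedefault="directed")
    for n in g.nodes:
        node = ET.SubElement(graph, "node", id=n)
        if table is not None:
            d = ET.SubElement(node, "data", key="epoque")
            d.text = str(table.epoque_of(n))
    for e in g.edges():
        src, dst = (e.tail, e.head) if e.directed else (e.u, e.v)
        edge = ET.SubElement(graph, "edge", source=src, target=dst)
        ET.SubElement(edge, "data", key="provenance").text = e.provenance
        ET.SubElement(edge, "data", key="directed").text = (
            "true" if e.directed else "false"
        )
        if stability is not None:
            val = stability.get(frozenset((e.u, e.v)))
            if val is not None:
                ET.SubElement(edge, "data", key="stability").text = f"{val:.1f}"
    ET.ElementTree(graphml).write(path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All tunables of one discovery run, mirrored into the run log."""

    target: Optional[str] = None
    alpha: float = 0.05
    max_k: int = 3
    bootstrap: int = 100
    path_len: int = 4
    seed: int = 0
    missing_sentinel: str = "NA"
    ci_method: str = "fisherz"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.max_k < 0 or self.bootstrap < 1 or self.path_len < 1:
            raise ValidationError("max_k >= 0, bootstrap >= 1, path_len >= 1 required")


def read_config(path: str | Path) -> RunConfig:
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def write_run_log(config: RunConfig, path: str | Path, **extra) -> None:
    payload = {"config": dataclasses.asdict(config), **extra}
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_json_report(obj, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.generic):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    return str(o)
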