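"""Core containers: variable metadata, tabular data, partially directed graphs.

The pipeline's variables are survey-style measurements taken in one of eight
time *epoques* (ordinal measurement periods).  Causal edges may never point
from a later epoque into an earlier one; that temporal constraint and the
variable's numeric type (binary / ordinal / cardinal) are the per-variable
metadata carried by :class:`VariableTable`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional

import networkx as nx
import numpy as np
import pandas as pd

VTYPES = ("binary", "ordinal", "cardinal")
EPOQUE_MIN, EPOQUE_MAX = 1, 8
NAME_RE = re.compile(r"^[A-Za-z0-9_.:-]+$")

PROVENANCES = ("temporal", "collider", "meek", "none")


class ValidationError(ValueError):
    """An object violates a structural invariant."""


class FormatError(ValueError):
    """A file could not be parsed in the expected dialect."""


class SchemaError(ValueError):
    """Columns of a data file disagree with the variable table."""


@dataclass(frozen=True)
class Variable:
    name: str
    vtype: str
    epoque: int

    def __post_init__(self) -> None:
        if not self.name or not NAME_RE.match(self.name):
            raise ValidationError(
                f"variable name {self.name!r} is empty or contains characters "
                "outside [A-Za-z0-9_.:-]"
            )
        if self.vtype not in VTYPES:
            raise ValidationError(
                f"variable {self.name!r}: vtype {self.vtype!r} not in {VTYPES}"
            )
        if not (EPOQUE_MIN <= int(self.epoque) <= EPOQUE_MAX):
            raise ValidationError(
                f"variable {self.name!r}: epoque {self.epoque} outside "
                f"{EPOQUE_MIN}..{EPOQUE_MAX}"
            )


class VariableTable:
    """Ordered per-variable metadata (numeric type and time epoque)."""

    def __init__(self, entries: Iterable[Variable | tuple]) -> None:
        parsed = []
        for e in entries:
            if not isinstance(e, Variable):
                e = Variable(*e)
            parsed.append(e)
        names = [e.name for e in parsed]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate variable names: {sorted(dupes)}")
        self.entries: list[Variable] = parsed
        self._by_name = {e.name: e for e in parsed}

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Variable]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Variable:
        return self._by_name[name]

    def epoque_of(self, name: str) -> int:
        return self._by_name[name].epoque

    def vtype_of(self, name: str) -> str:
        return self._by_name[name].vtype

    def subset(self, names: Iterable[str]) -> "VariableTable":
        keep = set(names)
        return VariableTable([e for e in self.entries if e.name in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "vtype": [e.vtype for e in self.entries],
                "epoque": [e.epoque for e in self.entries],
            }
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, VariableTable) and self.entries == other.entries


class Dataset:
    """Numeric data matrix with per-cell missingness, aligned to a VariableTable.

    Values are stored as a float ndarray with NaN marking missing cells;
    binary/ordinal columns carry integer codes in their observed cells.
    """

    def __init__(
        self,
        values: np.ndarray | pd.DataFrame,
        table: VariableTable,
        row_ids: Optional[list] = None,
    ) -> None:
        if isinstance(values, pd.DataFrame):
            if list(values.columns) != table.names:
                values = values[table.names]
            arr = values.to_numpy(dtype=float)
            if row_ids is None:
                row_ids = list(values.index)
        else:
            arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("data matrix must be 2-dimensional")
        n, p = arr.shape
        if n < 1 or p < 2:
            raise ValidationError(
                f"data matrix must have >= 1 row and >= 2 columns, got {n}x{p}"
            )
        if p != len(table):
            raise ValidationError(
                f"matrix has {p} columns but variable table has {len(table)}"
            )
        for j, var in enumerate(table):
            if var.vtype in ("binary", "ordinal"):
                col = arr[:, j]
                obs = col[~np.isnan(col)]
                if obs.size and not np.allclose(obs, np.round(obs)):
                    raise ValidationError(
                        f"column {var.name!r} is {var.vtype} but has "
                        "non-integer observed values"
                    )
        self.values = arr
        self.table = table
        self.row_ids = list(row_ids) if row_ids is not None else list(range(n))
        if len(self.row_ids) != n:
            raise ValidationError("row_ids length does not match row count")
        self._col_index = {name: j for j, name in enumerate(table.names)}

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def columns(self) -> list[str]:
        return self.table.names

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self._col_index[name]]

    def col_index(self, name: str) -> int:
        return self._col_index[name]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def n_missing_per_column(self) -> dict[str, int]:
        miss = self.missing_mask().sum(axis=0)
        return {name: int(miss[j]) for name, j in self._col_index.items()}

    def drop_columns(self, names: Iterable[str]) -> "Dataset":
        drop = set(names)
        keep = [n for n in self.columns if n not in drop]
        idx = [self._col_index[n] for n in keep]
        return Dataset(self.values[:, idx], self.table.subset(keep), self.row_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns, index=self.row_ids)


@dataclass(frozen=True)
class Edge:
    """One adjacency.  ``head`` is the arrow-head node, or None if undirected."""

    u: str
    v: str
    head: Optional[str] = None
    provenance: str = "none"

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValidationError(f"self-loop on {self.u!r}")
        if self.head is not None and self.head not in (self.u, self.v):
            raise ValidationError("edge head must be one of its endpoints")
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def tail(self) -> Optional[str]:
        if self.head is None:
            return None
        return self.v if self.head == self.u else self.u

    @property
    def directed(self) -> bool:
        return self.head is not None

    @property
    def key(self) -> frozenset:
        return frozenset((self.u, self.v))


class PartiallyDirectedGraph:
    """Skeleton plus orientations with per-edge provenance and sepsets.

    Invariants enforced on demand via :meth:`validate`: no self-loops, one
    edge per pair, acyclic directed part, and (given a table) no directed
    edge from a later epoque into an earlier one.
    """

    def __init__(self, nodes: Iterable[str] = ()) -> None:
        self._nodes: dict[str, None] = {}
        self._edges: dict[frozenset, Edge] = {}
        self._adj: dict[str, set[str]] = {}
        self.sepsets: dict[frozenset, frozenset] = {}
        for n in nodes:
            self.add_node(n)

    # -- construction ------------------------------------------------------
    def add_node(self, name: str) -> None:
        if name not in self._nodes:
            self._nodes[name] = None
            self._adj[name] = set()

    def add_edge(self, u: str, v: str, head: Optional[str] = None,
                 provenance: str = "none") -> None:
        self.add_node(u)
        self.add_node(v)
        key = frozenset((u, v))
        if key in self._edges:
            raise ValidationError(f"edge {u!r}--{v!r} already present")
        a, b = sorted((u, v))
        self._edges[key] = Edge(a, b, head, provenance)
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        key = frozenset((u, v))
        del self._edges[key]
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    def set_sepset(self, u: str, v: str, S: Iterable[str]) -> None:
        self.sepsets[frozenset((u, v))] = frozenset(S)

    def sepset(self, u: str, v: str) -> Optional[frozenset]:
        return self.sepsets.get(frozenset((u, v)))

    def orient(self, tail: str, head: str, provenance: str) -> None:
        """Direct the existing edge tail->head; error if absent or conflicting."""
        key = frozenset((tail, head))
        e = self._edges.get(key)
        if e is None:
            raise ValidationError(f"no edge between {tail!r} and {head!r}")
        if e.head is not None:
            if e.head != head:
                raise ValidationError(
                    f"edge {tail!r}-{head!r} already oriented the other way"
                )
            return
        self._edges[key] = replace(e, head=head, provenance=provenance)

    # -- queries -----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self) -> list[Edge]:
        """Edges in deterministic (lexicographic endpoint) order."""
        return [self._edges[k] for k in sorted(self._edges, key=sorted)]

    def edge(self, u: str, v: str) -> Optional[Edge]:
        return self._edges.get(frozenset((u, v)))

    def is_adjacent(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def has_directed_edge(self, tail: str, head: str) -> bool:
        e = self.edge(tail, head)
        return e is not None and e.head == head

    def neighbors(self, v: str) -> list[str]:
        return sorted(self._adj[v])

    def parents(self, v: str) -> list[str]:
        return sorted(u for u in self._adj[v] if self.has_directed_edge(u, v))

    def children(self, v: str) -> list[str]:
        return sorted(u for u in self._adj[v] if self.has_directed_edge(v, u))

    def undirected_neighbors(self, v: str) -> list[str]:
        out = []
        for u in self._adj[v]:
            e = self.edge(u, v)
            if e is not None and e.head is None:
                out.append(u)
        return sorted(out)

    def copy(self) -> "PartiallyDirectedGraph":
        g = PartiallyDirectedGraph(self._nodes)
        g._edges = dict(self._edges)
        g._adj = {k: set(v) for k, v in self._adj.items()}
        g.sepsets = dict(self.sepsets)
        return g

    def induced_subgraph(self, nodes: Iterable[str]) -> "PartiallyDirectedGraph":
        keep = set(nodes)
        g = PartiallyDirectedGraph(n for n in self._nodes if n in keep)
        for e in self.edges():
            if e.u in keep and e.v in keep:
                g.add_edge(e.u, e.v, e.head, e.provenance)
        for key, S in self.sepsets.items():
            if key <= keep:
                g.sepsets[key] = S
        return g

    def directed_part(self) -> nx.DiGraph:
        dg = nx.DiGraph()
        dg.add_nodes_from(self._nodes)
        for e in self.edges():
            if e.directed:
                dg.add_edge(e.tail, e.head)
        return dg

    def skeleton_pairs(self) -> set[frozenset]:
        return set(self._edges)

    def creates_cycle(self, tail: str, head: str) -> bool:
        """Would orienting tail->head close a directed cycle?"""
        # cycle iff a directed path head ~> tail already exists
        seen = {head}
        stack = [head]
        while stack:
            cur = stack.pop()
            if cur == tail:
                return True
            for c in self.children(cur):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def provenance_counts(self) -> dict[str, int]:
        counts = {"temporal": 0, "collider": 0, "meek": 0, "unoriented": 0}
        for e in self._edges.values():
            counts[e.provenance if e.directed else "unoriented"] += 1
        return counts

    # -- validation --------------------------------------------------------
    def validate(self, table: Optional[VariableTable] = None) -> None:
        dg = self.directed_part()
        if not nx.is_directed_acyclic_graph(dg):
            cyc = nx.find_cycle(dg)
            raise ValidationError(f"directed part contains a cycle: {cyc}")
        for key, S in self.sepsets.items():
            if key in self._edges:
                u, v = sorted(key)
                raise ValidationError(
                    f"pair {u!r},{v!r} has both an edge and a sepset {sorted(S)}"
                )
        if table is not None:
            for e in self.edges():
                if e.directed and table.epoque_of(e.tail) > table.epoque_of(e.head):
                    raise ValidationError(
                        f"edge {e.tail}->{e.head} points from epoque "
                        f"{table.epoque_of(e.tail)} back to "
                        f"{table.epoque_of(e.head)}"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PartiallyDirectedGraph):
            return NotImplemented
        return (
            set(self._nodes) == set(other._nodes)
            and self._edges == other._edges
        )
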