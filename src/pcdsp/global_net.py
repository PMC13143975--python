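"""Global network assembly and edge orientation.

The global skeleton is the union of symmetric local parents-and-children
sets.  Orientation then proceeds in three phases with strict precedence:

1. temporal — edges between distinct time epoques point forward in time
   (time order is treated as known fact and is never overruled);
2. collider — unshielded triples A—C—B with C outside sepset(A, B) become
   A→C←B, unless that contradicts an existing orientation, the epoque
   order, or acyclicity (then the triple is skipped and logged);
3. meek — Meek rules R1–R4 propagate orientations to a fixed point.

Every directed edge carries the provenance of the phase that oriented it;
conflicts are logged, never silently overwritten.  Iteration order is
lexicographic throughout, so identical inputs give identical graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .citest import CITester, FisherZTester
from .datamodel import Dataset, PartiallyDirectedGraph, ValidationError, VariableTable
from .local import PCSet, gll_pc, symmetry_correct


@dataclass
class OrientationReport:
    """Provenance accounting for one learned network."""

    counts: dict[str, int] = field(default_factory=dict)
    conflicts: list[dict] = field(default_factory=list)

    @property
    def total_edges(self) -> int:
        return sum(self.counts.values())

    @property
    def n_oriented(self) -> int:
        return self.total_edges - self.counts.get("unoriented", 0)

    def percent(self, provenance: str) -> float:
        total = self.total_edges
        return 100.0 * self.counts.get(provenance, 0) / total if total else 0.0


def assemble_skeleton(pcsets: dict[str, PCSet]) -> PartiallyDirectedGraph:
    """Undirected skeleton from symmetric PC sets, sepsets merged in."""
    for x, pcx in pcsets.items():
        for y in pcx.members:
            if y in pcsets and x not in pcsets[y].members:
                raise ValidationError(
                    f"asymmetric PC sets: {y!r} in PC({x!r}) but not conversely"
                )
    g = PartiallyDirectedGraph(sorted(pcsets))
    for x in sorted(pcsets):
        for y in sorted(pcsets[x].members):
            if x < y:
                g.add_edge(x, y)
    for pc in pcsets.values():
        for key, S in pc.sepsets.items():
            if key not in g.skeleton_pairs():
                g.sepsets.setdefault(key, S)
    return g


def orient_temporal(
    g: PartiallyDirectedGraph, table: VariableTable
) -> PartiallyDirectedGraph:
    """Point every cross-epoque edge forward in time."""
    out = g.copy()
    for e in out.edges():
        eu, ev = table.epoque_of(e.u), table.epoque_of(e.v)
        if eu == ev or e.directed:
            continue
        tail, head = (e.u, e.v) if eu < ev else (e.v, e.u)
        out.orient(tail, head, "temporal")
    return out


def orient_colliders(
    g: PartiallyDirectedGraph,
    table: Optional[VariableTable] = None,
    conflicts: Optional[list] = None,
) -> PartiallyDirectedGraph:
    """Orient unshielded colliders A→C←B from recorded sepsets.

    A triple fires only if C is absent from sepset(A, B); it is skipped (and
    the conflict logged) when either arm would oppose an existing
    orientation, point backwards in time, or close a directed cycle.
    """
    out = g.copy()
    conflicts = conflicts if conflicts is not None else []
    for c in sorted(out.nodes):
        nbrs = out.neighbors(c)
        for i, a in enumerate(nbrs):
            for b in nbrs[i + 1:]:
                if out.is_adjacent(a, b):
                    continue
                sep = out.sepset(a, b)
                if sep is None:
                    raise ValidationError(
                        f"non-adjacent pair {a!r},{b!r} has no recorded sepset"
                    )
                if c in sep:
                    continue
                problem = _collider_conflict(out, a, b, c, table)
                if problem:
                    conflicts.append(
                        {
                            "rule": "collider",
                            "triple": (a, c, b),
                            "edge": problem[0],
                            "reason": problem[1],
                            "resolution": "skipped",
                        }
                    )
                    continue
                for tail in (a, b):
                    if not out.has_directed_edge(tail, c):
                        out.orient(tail, c, "collider")
    return out


def _collider_conflict(g, a, b, c, table):
    for tail in (a, b):
        if g.has_directed_edge(c, tail):
            return (f"{tail}-{c}", "existing opposite orientation")
        if table is not None and table.epoque_of(tail) > table.epoque_of(c):
            return (f"{tail}-{c}", "would point backwards in time")
    # orienting both arms into c cannot close a cycle unless one already
    # has a directed path from c back to the tail
    for tail in (a, b):
        if not g.has_directed_edge(tail, c) and g.creates_cycle(tail, c):
            return (f"{tail}-{c}", "would create a directed cycle")
    return None


def orient_meek(
    g: PartiallyDirectedGraph,
    table: Optional[VariableTable] = None,
    conflicts: Optional[list] = None,
) -> PartiallyDirectedGraph:
    """Apply Meek rules R1–R4 to a fixed point (provenance "meek").

    R1: a→x, x—y, a,y non-adjacent            ⇒ x→y
    R2: x→c, c→y, x—y                          ⇒ x→y
    R3: x—c→y, x—d→y, c,d non-adjacent, x—y    ⇒ x→y
    R4: x—c, c→d, d→y, c,y non-adjacent,
        x adjacent to d, x—y                   ⇒ x→y
    """
    out = g.copy()
    conflicts = conflicts if conflicts is not None else []
    changed = True
    while changed:
        changed = False
        for e in out.edges():
            if e.directed:
                continue
            for x, y in ((e.u, e.v), (e.v, e.u)):
                rule = _meek_rule_fires(out, x, y)
                if rule is None:
                    continue
                if table is not None and table.epoque_of(x) > table.epoque_of(y):
                    conflicts.append(
                        {"rule": rule, "edge": f"{x}-{y}",
                         "reason": "would point backwards in time",
                         "resolution": "skipped"}
                    )
                    continue
                if out.creates_cycle(x, y):
                    conflicts.append(
                        {"rule": rule, "edge": f"{x}-{y}",
                         "reason": "would create a directed cycle",
                         "resolution": "skipped"}
                    )
                    continue
                out.orient(x, y, "meek")
                changed = True
                break
    return out


def _meek_rule_fires(g, x, y):
    # R1
    for a in g.parents(x):
        if not g.is_adjacent(a, y):
            return "meek_r1"
    # R2
    for c in g.children(x):
        if g.has_directed_edge(c, y):
            return "meek_r2"
    # R3
    into_y = [c for c in g.undirected_neighbors(x) if g.has_directed_edge(c, y)]
    for i, c in enumerate(into_y):
        for d in into_y[i + 1:]:
            if not g.is_adjacent(c, d):
                return "meek_r3"
    # R4
    for c in g.undirected_neighbors(x):
        if g.is_adjacent(c, y):
            continue
        for d in g.children(c):
            if g.has_directed_edge(d, y) and g.is_adjacent(x, d):
                return "meek_r4"
    return None


def build_global_network(
    data: Optional[Dataset],
    table: VariableTable,
    alpha: float = 0.05,
    max_k: int = 3,
    tester: Optional[CITester] = None,
    symmetry_rule: str = "AND",
) -> tuple[PartiallyDirectedGraph, OrientationReport]:
    """Full pipeline: local PC sets → symmetry → skeleton → orientation.

    ``tester`` defaults to Fisher-z on the data; pass an
    :class:`~pcdsp.citest.OracleCITester` for noiseless benchmarking.
    """
    if tester is None:
        if data is None:
            raise ValidationError("either data or a tester must be provided")
        tester = FisherZTester(data, alpha)
    variables = [v for v in tester.variables if v in table]
    if len(variables) < 2:
        raise ValidationError("need at least 2 variables to learn a network")

    pcsets = {v: gll_pc(tester, v, max_k, variables) for v in sorted(variables)}
    pcsets = symmetry_correct(pcsets, symmetry_rule)

    conflicts: list[dict] = []
    g = assemble_skeleton(pcsets)
    g = orient_temporal(g, table)
    g = orient_colliders(g, table, conflicts)
    g = orient_meek(g, table, conflicts)
    g.validate(table)

    report = OrientationReport(counts=g.provenance_counts(), conflicts=conflicts)
    return g, report
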