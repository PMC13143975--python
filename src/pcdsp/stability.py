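"""Bootstrap edge stability, causal-path enumeration, and intervention-impact
ranking.

Stability: resample the rows with replacement B times (default 100), relearn
the whole network per replicate, and score each adjacency by the percentage
of replicates in which it was detected.  Replicates draw from independent
deterministic substreams of the master seed, so the b-th replicate is the
same regardless of B or execution order.

Paths/impact: enumerate every directed simple path of 1..max_len edges that
terminates at the target (default max_len 4, excluding distal influence),
then rank each node by the fraction of those paths that disappear when the
node and its incident edges are deleted — a heuristic proxy for the reach of
an intervention on that node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .citest import CITester, FisherZTester
from .datamodel import Dataset, PartiallyDirectedGraph, VariableTable
from .global_net import build_global_network


@dataclass
class EdgeStabilityTable:
    """Per-adjacency detection percentages over B bootstrap networks."""

    percents: dict[frozenset, float]
    B: int
    seed: int
    orientation_aware: bool = False

    def percent(self, u: str, v: str) -> float:
        return self.percents.get(frozenset((u, v)), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.percents, key=sorted):
            u, v = sorted(key)
            rows.append({"u": u, "v": v, "stability_pct": self.percents[key]})
        return pd.DataFrame(rows, columns=["u", "v", "stability_pct"])


def bootstrap_stability(
    data: Dataset,
    table: VariableTable,
    alpha: float = 0.05,
    max_k: int = 3,
    B: int = 100,
    seed: int = 0,
    tester_factory: Optional[Callable[[Dataset], CITester]] = None,
    full_graph: Optional[PartiallyDirectedGraph] = None,
) -> EdgeStabilityTable:
    """Detection percentage of every adjacency over B bootstrap networks.

    Scoring is orientation-agnostic: an adjacency counts as detected
    whichever way (or whether) it is oriented in the replicate, since
    orientation provenance varies across resamples.  The table covers the
    union of the full-data graph's adjacencies and anything seen in at
    least one replicate.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if tester_factory is None:
        tester_factory = lambda d: FisherZTester(d, alpha)
    if full_graph is None:
        full_graph, _ = build_global_network(
            data, table, alpha, max_k, tester=tester_factory(data)
        )
    counts: dict[frozenset, int] = {k: 0 for k in full_graph.skeleton_pairs()}
    children = np.random.SeedSequence(seed).spawn(B)
    n = data.n_rows
    for b in range(B):
        rng = np.random.default_rng(children[b])
        idx = rng.integers(0, n, size=n)
        boot = Dataset(data.values[idx], table)
        g_b, _ = build_global_network(
            boot, table, alpha, max_k, tester=tester_factory(boot)
        )
        for key in g_b.skeleton_pairs():
            counts[key] = counts.get(key, 0) + 1
    percents = {k: 100.0 * c / B for k, c in counts.items()}
    return EdgeStabilityTable(percents=percents, B=B, seed=seed)


@dataclass
class PathImpactTable:
    """Directed simple paths into the target and per-node elimination shares."""

    target: str
    max_len: int
    paths: list[tuple[str, ...]] = field(default_factory=list)
    eliminated_fraction: dict[str, float] = field(default_factory=dict)
    ranking: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"node": n, "eliminated_fraction": f} for n, f in self.ranking],
            columns=["node", "eliminated_fraction"],
        )


def enumerate_paths(
    g: PartiallyDirectedGraph,
    target: str,
    max_len: int = 4,
    traverse_undirected: bool = False,
) -> PathImpactTable:
    """All directed simple paths of 1..max_len edges terminating at target.

    Undirected edges are excluded by default (an undirected traversal would
    count non-causal routes as causal); set ``traverse_undirected`` to walk
    them in both directions.
    """
    if target not in g:
        raise KeyError(f"target {target!r} not in graph")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    paths: list[tuple[str, ...]] = []

    def upstream(node: str) -> list[str]:
        pre = g.parents(node)
        if traverse_undirected:
            pre = sorted(set(pre) | set(g.undirected_neighbors(node)))
        return pre

    def extend(path: tuple[str, ...]) -> None:
        # path[0] is the current upstream end; path[-1] is the target
        if len(path) > 1:
            paths.append(path)
        if len(path) - 1 >= max_len:
            return
        for p in upstream(path[0]):
            if p not in path:
                extend((p,) + path)

    extend((target,))
    paths.sort(key=lambda p: (len(p), p))
    return PathImpactTable(target=target, max_len=max_len, paths=paths)


def impact_ranking(table: PathImpactTable) -> PathImpactTable:
    """Rank nodes by the fraction of paths eliminated when each is deleted.

    Deleting a node removes all its incident edges, so the eliminated paths
    are exactly those containing it.  Ties break lexicographically; the
    target itself is excluded.
    """
    if not table.paths:
        warnings.warn(
            f"no directed paths into {table.target!r}; empty ranking",
            stacklevel=2,
        )
        table.eliminated_fraction = {}
        table.ranking = []
        return table
    total = len(table.paths)
    counts: dict[str, int] = {}
    for path in table.paths:
        for node in path[:-1]:  # exclude the terminal target
            counts[node] = counts.get(node, 0) + 1
    fractions = {n: c / total for n, c in counts.items()}
    table.eliminated_fraction = fractions
    table.ranking = sorted(
        fractions.items(), key=lambda kv: (-kv[1], kv[0])
    )
    return table
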