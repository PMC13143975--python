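"""Synthetic tiered-DAG benchmark generator.

Emulates the statistical shape of a longitudinal developmental cohort: a
ground-truth DAG over variables assigned to eight time epoques (edges never
point from a later epoque to an earlier one), linear-Gaussian structural
equations with optional monotone quantile discretization into ordinal/binary
codes, MCAR missingness, and optional information-equivalent duplicate
columns for multiplicity testing.  An exact graphical d-separation oracle
over the ground truth makes every pipeline stage testable without real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .datamodel import Dataset, ValidationError, Variable, VariableTable

DEFAULT_MIN_WEIGHT = 0.3


@dataclass
class SimConfig:
    """Study-scale defaults emulate a 1,053-subject, 252-variable cohort
    observed over 8 epoques with an average degree near 6.5 and light MCAR
    missingness."""

    n_vars: int = 252
    n_rows: int = 1053
    epoque_count: int = 8
    edge_density: float = 0.026
    missing_rate: float = 0.05
    n_duplicates: int = 0
    seed: int = 0
    binary_fraction: float = 0.2
    ordinal_fraction: float = 0.3
    ordinal_levels: int = 5
    min_weight: float = DEFAULT_MIN_WEIGHT
    max_weight: float = 1.0
    noise_sd: float = 1.0
    max_in_degree: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_vars < 1 or self.n_rows < 1 or self.n_duplicates < 0:
            raise ValidationError("all counts must be positive")
        if not (1 <= self.epoque_count <= 8):
            raise ValidationError("epoque_count must be in 1..8")
        if not (0.0 <= self.missing_rate <= 0.9):
            raise ValidationError("missing_rate must lie in [0, 0.9]")
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValidationError("edge_density must lie in [0, 1]")
        if not (0 < self.min_weight <= self.max_weight):
            raise ValidationError("need 0 < min_weight <= max_weight")
        if self.binary_fraction + self.ordinal_fraction > 1.0 + 1e-9:
            raise ValidationError("binary_fraction + ordinal_fraction > 1")
        if self.ordinal_levels < 2:
            raise ValidationError("ordinal_levels must be >= 2")
        if self.n_duplicates > self.n_vars:
            raise ValidationError("cannot duplicate more variables than exist")
        if self.max_in_degree is not None and self.max_in_degree < 0:
            raise ValidationError("max_in_degree must be >= 0")


@dataclass
class GroundTruthModel:
    """A tiered DAG with linear-Gaussian mechanisms.

    ``dag`` covers the structural variables only; ``duplicates`` maps each
    deterministic copy's name to its source (copies sit outside the DAG and
    deliberately violate faithfulness, which is what multiplicity testing
    detects).
    """

    dag: nx.DiGraph
    epoque_of: dict[str, int]
    weights: dict[tuple[str, str], float]
    noise_sd: dict[str, float]
    vtypes: dict[str, str]
    ordinal_levels: int = 5
    duplicates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValidationError("ground-truth graph must be acyclic")
        for u, v in self.dag.edges:
            if self.epoque_of[u] > self.epoque_of[v]:
                raise ValidationError(
                    f"edge {u}->{v} points from epoque {self.epoque_of[u]} "
                    f"back to {self.epoque_of[v]}"
                )

    @property
    def variables(self) -> list[str]:
        return list(self.dag.nodes)

    @property
    def all_columns(self) -> list[str]:
        return list(self.dag.nodes) + list(self.duplicates)

    def variable_table(self) -> VariableTable:
        entries = [
            Variable(v, self.vtypes[v], self.epoque_of[v]) for v in self.variables
        ]
        for dup, src in self.duplicates.items():
            entries.append(Variable(dup, self.vtypes[src], self.epoque_of[src]))
        return VariableTable(entries)

    def skeleton_pairs(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.dag.edges}

    def true_markov_boundary(self, target: str) -> set[str]:
        """Parents, children and spouses of the target in the true DAG."""
        parents = set(self.dag.predecessors(target))
        children = set(self.dag.successors(target))
        spouses = set()
        for c in children:
            spouses |= set(self.dag.predecessors(c))
        return (parents | children | spouses) - {target}


def _variable_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"V{i:0{width}d}" for i in range(1, n + 1)]


def sample_model(cfg: SimConfig) -> GroundTruthModel:
    """Sample a tiered ground-truth DAG with linear-Gaussian mechanisms.

    Variables are assigned uniformly to epoques; candidate edges run only in
    epoque-nondecreasing direction (same-epoque pairs follow a fixed node
    order, keeping the graph acyclic by construction) and are kept with
    probability ``edge_density``.  Weights are uniform on ±[min_weight,
    max_weight] so faithfulness holds away from cancellations.
    """
    rng = np.random.default_rng(cfg.seed)
    names = _variable_names(cfg.n_vars)
    epoques = rng.integers(1, cfg.epoque_count + 1, size=cfg.n_vars)
    # topological construction order: epoque, then name
    order = sorted(range(cfg.n_vars), key=lambda i: (epoques[i], names[i]))

    dag = nx.DiGraph()
    dag.add_nodes_from(names)
    weights: dict[tuple[str, str], float] = {}
    cap = cfg.max_in_degree
    for pos_j, j in enumerate(order):
        for i in order[:pos_j]:
            if cap is not None and dag.in_degree(names[j]) >= cap:
                break
            if rng.random() < cfg.edge_density:
                w = rng.uniform(cfg.min_weight, cfg.max_weight)
                if rng.random() < 0.5:
                    w = -w
                dag.add_edge(names[i], names[j])
                weights[(names[i], names[j])] = float(w)

    if cfg.n_vars > 1 and dag.number_of_edges() == 0:
        warnings.warn(
            "sampled ground-truth graph has no edges (edge_density too low)",
            stacklevel=2,
        )

    u = rng.random(cfg.n_vars)
    vtypes = {}
    for i, name in enumerate(names):
        if u[i] < cfg.binary_fraction:
            vtypes[name] = "binary"
        elif u[i] < cfg.binary_fraction + cfg.ordinal_fraction:
            vtypes[name] = "ordinal"
        else:
            vtypes[name] = "cardinal"

    duplicates: dict[str, str] = {}
    if cfg.n_duplicates:
        sources = rng.choice(names, size=cfg.n_duplicates, replace=False)
        for k, src in enumerate(sorted(sources), start=1):
            duplicates[f"{src}.dup"] = src

    return GroundTruthModel(
        dag=dag,
        epoque_of={names[i]: int(epoques[i]) for i in range(cfg.n_vars)},
        weights=weights,
        noise_sd={n: cfg.noise_sd for n in names},
        vtypes=vtypes,
        ordinal_levels=cfg.ordinal_levels,
        duplicates=duplicates,
    )


def sample_data(
    model: GroundTruthModel,
    n_rows: int,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[Dataset, VariableTable]:
    """Draw i.i.d. rows from the structural equations in topological order.

    Discrete nodes are produced by monotone quantile discretization of the
    node's linear-Gaussian response; downstream children consume the observed
    (discretized) codes, so the conditional-independence structure of the
    observed data matches d-separation on the DAG exactly.  Duplicate columns
    are computed from their source after generation; the MCAR mask is applied
    uniformly per cell afterwards.
    """
    if not (0.0 <= missing_rate <= 0.9):
        raise ValidationError("missing_rate must lie in [0, 0.9]")
    rng = np.random.default_rng(seed)
    topo = list(nx.topological_sort(model.dag))
    columns: dict[str, np.ndarray] = {}
    for v in topo:
        latent = rng.normal(0.0, model.noise_sd[v], size=n_rows)
        for p in model.dag.predecessors(v):
            latent = latent + model.weights[(p, v)] * columns[p]
        columns[v] = _discretize(latent, model.vtypes[v], model.ordinal_levels)
    for dup, src in model.duplicates.items():
        columns[dup] = columns[src].copy()

    table = model.variable_table()
    values = np.column_stack([columns[name] for name in table.names])
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = values.astype(float)
        values[mask] = np.nan
    return Dataset(values, table), table


def _discretize(x: np.ndarray, vtype: str, levels: int) -> np.ndarray:
    if vtype == "cardinal":
        return x
    k = 2 if vtype == "binary" else levels
    # monotone quantile cut into k codes 0..k-1
    qs = np.quantile(x, np.linspace(0, 1, k + 1)[1:-1])
    return np.searchsorted(qs, x, side="left").astype(float)


def d_separated(
    model: GroundTruthModel | nx.DiGraph,
    x: str,
    y: str,
    S: Iterable[str] = (),
) -> bool:
    """Exact graphical d-separation of x and y given S on the ground truth.

    Standard reachability over active trails: chains and forks are blocked by
    conditioning, colliders are opened by conditioning on the collider or any
    of its descendants.
    """
    dag = model.dag if isinstance(model, GroundTruthModel) else model
    S = frozenset(S)
    for v in (x, y, *S):
        if v not in dag:
            raise KeyError(f"unknown variable {v!r}")
    if x == y:
        raise ValueError("x and y must be distinct")
    if x in S or y in S:
        raise ValueError("x and y must not be members of S")

    # ancestors of S (inclusive): colliders in this set pass information
    anc_s = set(S)
    stack = list(S)
    while stack:
        v = stack.pop()
        for p in dag.predecessors(v):
            if p not in anc_s:
                anc_s.add(p)
                stack.append(p)

    # states (node, direction): 'up' = trail leaves via this node's tails,
    # 'down' = trail arrived along an edge into the node
    visited: set[tuple[str, str]] = set()
    frontier: list[tuple[str, str]] = [(x, "up")]
    while frontier:
        v, direction = frontier.pop()
        if (v, direction) in visited:
            continue
        visited.add((v, direction))
        if v == y:
            return False
        if direction == "up" and v not in S:
            for p in dag.predecessors(v):
                frontier.append((p, "up"))
            for c in dag.successors(v):
                frontier.append((c, "down"))
        elif direction == "down":
            if v not in S:
                for c in dag.successors(v):
                    frontier.append((c, "down"))
            if v in anc_s:
                for p in dag.predecessors(v):
                    frontier.append((p, "up"))
    return True
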