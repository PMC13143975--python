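"""Independent oracles and small utilities shared across the test suite.

Everything here deliberately avoids the library's own code paths: path
counting goes through networkx, orientation consensus through exhaustive
enumeration of DAG extensions, d-separation checks through
``nx.is_d_separator``.  These are the yardsticks the implementation is
measured against.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from pcdsp import SimConfig, sample_model


def random_tiered_model(rng, n_lo=4, n_hi=15, max_in_degree=3,
                        density=(0.2, 0.5), epoques=(1, 8), **kw):
    """One random ground-truth model with bounded in-degree."""
    n = int(rng.integers(n_lo, n_hi + 1))
    cfg = SimConfig(
        n_vars=n,
        n_rows=10,
        epoque_count=int(rng.integers(epoques[0], epoques[1] + 1)),
        edge_density=float(rng.uniform(*density)),
        max_in_degree=max_in_degree,
        seed=int(rng.integers(2**31 - 1)),
        **kw,
    )
    return sample_model(cfg)


def consensus_orientations(skel_pairs, sepsets, epoque_of):
    """Brute-force orientation consensus over all consistent DAG extensions.

    An extension is a DAG with the given skeleton, no edge pointing from a
    later epoque to an earlier one, and unshielded colliders exactly where
    the middle node is absent from the pair's sepset.  An edge's consensus
    direction is the one shared by every extension, or None if they disagree.
    """
    edges = [tuple(sorted(k)) for k in sorted(skel_pairs, key=sorted)]
    adj: dict[str, set] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    triples = []
    for c in adj:
        for a, b in itertools.combinations(sorted(adj[c]), 2):
            if b not in adj[a]:
                triples.append((a, c, b))
    valid = []
    for bits in itertools.product((0, 1), repeat=len(edges)):
        ok = True
        dirs = []
        for (u, v), bit in zip(edges, bits):
            t, h = (u, v) if bit == 0 else (v, u)
            if epoque_of[t] > epoque_of[h]:
                ok = False
                break
            dirs.append((t, h))
        if not ok:
            continue
        G = nx.DiGraph()
        G.add_nodes_from(adj)
        G.add_edges_from(dirs)
        if not nx.is_directed_acyclic_graph(G):
            continue
        for a, c, b in triples:
            is_collider = G.has_edge(a, c) and G.has_edge(b, c)
            if is_collider != (c not in sepsets[frozenset((a, b))]):
                ok = False
                break
        if ok:
            valid.append(G)
    assert valid, "no DAG extension consistent with skeleton+tiers+sepsets"
    out = {}
    for u, v in edges:
        seen = {((u, v) if G.has_edge(u, v) else (v, u)) for G in valid}
        out[(u, v)] = seen.pop() if len(seen) == 1 else None
    return out


def nx_directed_paths_into(g, target, max_len):
    """Exhaustive directed simple paths of 1..max_len edges ending at target,
    via networkx (independent of the package's DFS)."""
    dg = g.directed_part()
    found = set()
    for src in dg.nodes:
        if src == target:
            continue
        for path in nx.all_simple_paths(dg, src, target, cutoff=max_len):
            found.add(tuple(path))
    return found


def skeleton_f1(true_pairs, got_pairs):
    tp = len(true_pairs & got_pairs)
    prec = tp / max(1, len(got_pairs))
    rec = tp / max(1, len(true_pairs))
    if prec + rec == 0:
        return 0.0
    return 2 * prec * rec / (prec + rec)


def add_duplicate_column(data, table, source, suffix=".dup"):
    """Return (data, table) with an exact copy of one column appended."""
    from pcdsp import Dataset, Variable, VariableTable

    name = source + suffix
    entries = list(table.entries) + [
        Variable(name, table.vtype_of(source), table.epoque_of(source))
    ]
    new_table = VariableTable(entries)
    values = np.column_stack([data.values, data.column(source)])
    return Dataset(values, new_table), new_table
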