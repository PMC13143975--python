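#!/usr/bin/env python
"""Local causal model of the late-epoque outcome, with multiplicity screen.

Picks the epoque-8 variable with the largest ground-truth Markov boundary
as the study outcome (the analogue of a late-wave symptom score), reads its
boundary off the learned network, re-discovers it directly from data, and
runs the TIE*-style multiplicity screen twice: on the cohort as simulated
(expected: unique) and after injecting an information-equivalent duplicate
of one boundary member (expected: multiple).  Writes
results/markov_boundary.json.
"""

import json
from pathlib import Path

import numpy as np

from pcdsp import (
    Dataset,
    FisherZTester,
    Variable,
    VariableTable,
    discover_markov_boundary,
    extract_markov_boundary,
    read_dataset,
    read_network,
    read_variable_table,
    tie_star_multiplicity,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_variable_table(ROOT / "cohort" / "variables.csv")
    data = read_dataset(ROOT / "cohort" / "data.csv", table)
    graph = read_network(ROOT / "network" / "network.tsv")
    truth = read_network(ROOT / "cohort" / "ground_truth_edges.tsv")
    for name in table.names:  # edge lists omit isolated nodes
        graph.add_node(name)
        truth.add_node(name)

    last = max(e.epoque for e in table)
    target = max(
        (v.name for v in table if v.epoque == last),
        key=lambda v: (len(extract_markov_boundary(truth, v).boundary), v),
    )
    mb = extract_markov_boundary(graph, target)
    tester = FisherZTester(data)
    discovered = discover_markov_boundary(tester, target)
    clean = tie_star_multiplicity(tester, target)

    src = sorted(discovered)[0]
    entries = list(table.entries) + [
        Variable(src + ".dup", table.vtype_of(src), table.epoque_of(src))
    ]
    dup_table = VariableTable(entries)
    dup_data = Dataset(
        np.column_stack([data.values, data.column(src)]), dup_table
    )
    dup = tie_star_multiplicity(FisherZTester(dup_data), target)

    payload = {
        "target": target,
        "direct_causes": sorted(mb.direct_causes),
        "direct_effects": sorted(mb.direct_effects),
        "spouses": sorted(mb.spouses),
        "undirected_neighbors": sorted(mb.undirected_neighbors),
        "boundary_from_graph": sorted(mb.boundary),
        "boundary_from_data": sorted(discovered),
        "multiplicity_clean": {
            "unique": clean.unique,
            "n_boundaries": len(clean.boundaries),
        },
        "multiplicity_with_duplicate_of": src,
        "multiplicity_duplicate": {
            "unique": dup.unique,
            "n_boundaries": len(dup.boundaries),
            "boundaries": [sorted(b) for b in dup.boundaries],
        },
    }
    (ROOT / "markov_boundary.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )
    print(
        f"outcome {target}: {len(mb.direct_causes)} direct causes, "
        f"{len(mb.direct_effects)} direct effects, {len(mb.spouses)} spouses, "
        f"{len(mb.undirected_neighbors)} undirected"
    )
    print(
        f"multiplicity: clean cohort -> "
        f"{'unique' if clean.unique else 'MULTIPLE'}; with duplicated "
        f"{src} -> {len(dup.boundaries)} boundaries"
    )


if __name__ == "__main__":
    main()
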