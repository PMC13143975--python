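"""Markov boundary extraction and multiplicity testing.

The Markov boundary of a target is the smallest variable set carrying all
the information about it: under faithfulness, its direct causes, direct
effects, and the direct causes of its direct effects (spouses).  A learned
partially directed graph yields the boundary read-off in
:func:`extract_markov_boundary`; :func:`discover_markov_boundary` finds it
directly from data via local discovery.

Faithfulness can fail through *multiplicity* — several distinct Markov
boundaries for one target, typically caused by information-equivalent
(e.g. duplicated or recoded) variables.  :func:`tie_star_multiplicity`
screens for it TIE*-style: hide small subsets of already-discovered
boundary members, re-run the discovery, and accept an alternative boundary
when the target is rendered independent of the original boundary given the
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .citest import CITester
from .datamodel import PartiallyDirectedGraph
from .local import gll_pc


@dataclass
class MultiplicityVerdict:
    unique: bool
    boundaries: list[frozenset]
    hidden_sets_tested: int = 0
    details: list[dict] = field(default_factory=list)


@dataclass
class MarkovBoundaryReport:
    """The local causal network model of one target."""

    target: str
    direct_causes: frozenset
    direct_effects: frozenset
    spouses: frozenset
    undirected_neighbors: frozenset
    local_graph: PartiallyDirectedGraph
    multiplicity: Optional[MultiplicityVerdict] = None

    @property
    def boundary(self) -> frozenset:
        return (
            self.direct_causes
            | self.direct_effects
            | self.spouses
            | self.undirected_neighbors
        )


def extract_markov_boundary(
    g: PartiallyDirectedGraph, target: str
) -> MarkovBoundaryReport:
    """Read the target's Markov boundary off a learned graph.

    Undirected neighbors are included as a conservative superset and
    reported separately (the graph could not commit to a direction).  The
    four sets are disjoint by construction: causes, then effects, then
    spouses, then undirected neighbors.
    """
    if target not in g:
        raise KeyError(f"target {target!r} not in graph")
    causes = set(g.parents(target))
    effects = set(g.children(target))
    spouses: set[str] = set()
    for c in sorted(effects):
        spouses |= set(g.parents(c))
    spouses -= causes | effects | {target}
    undirected = set(g.undirected_neighbors(target)) - causes - effects - spouses
    mb = causes | effects | spouses | undirected
    return MarkovBoundaryReport(
        target=target,
        direct_causes=frozenset(causes),
        direct_effects=frozenset(effects),
        spouses=frozenset(spouses),
        undirected_neighbors=frozenset(undirected),
        local_graph=g.induced_subgraph(mb | {target}),
    )


def discover_markov_boundary(
    tester: CITester, target: str, max_k: int = 3
) -> frozenset:
    """Markov boundary straight from data (HITON-MB style).

    Parents-and-children via local discovery with the AND-symmetry filter
    (y stays only if the target is in PC(y) too), then spouse recovery: a
    candidate x adjacent to some member y (but not to the target) is a
    spouse if conditioning on y re-activates the dependence between x and
    the target given x's recorded sepset — the collider signature.  A final
    backward pass re-tests every spouse against the rest of the boundary
    and drops those rendered independent; this removes candidates admitted
    through longer collider chains and keeps exactly one representative of
    any information-equivalent pair.
    """
    runs: dict[str, object] = {}

    def pc_of(v):
        if v not in runs:
            runs[v] = gll_pc(tester, v, max_k)
        return runs[v]

    pc = pc_of(target)
    # AND-symmetry, except that a reverse-run "separation" produced by the
    # insufficiency path (zero residual variance, i.e. collinearity with an
    # information-equivalent twin) is not genuine asymmetry: discarding such
    # members would delete both representatives of a duplicated variable.
    members = {
        y for y in pc.members
        if target in pc_of(y).members
        or not _genuinely_separated(pc_of(y), target)
    }
    boundary = set(members)
    spouses: set[str] = set()
    for y in sorted(members):
        for x in sorted(pc_of(y).members - boundary - {target}):
            sep = pc.sepsets.get(frozenset((target, x)), frozenset())
            if y in sep or x in boundary:
                continue
            res = tester.test(target, x, sorted(sep | {y}))
            if not res.independent:
                boundary.add(x)
                spouses.add(x)
    changed = True
    while changed:
        changed = False
        for x in sorted(spouses & boundary):
            if tester.test(target, x, sorted(boundary - {x})).independent:
                boundary.discard(x)
                changed = True
    return frozenset(boundary)


def _genuinely_separated(run, other: str) -> bool:
    """Did this PC run separate ``other`` with a computable test (as opposed
    to an insufficiency outcome)?"""
    for entry in run.trace:
        if entry.variable == other and entry.action in (
            "remove", "reject_marginal"
        ):
            return entry.result is None or not entry.result.insufficient
    return True


def tie_star_multiplicity(
    tester: CITester,
    target: str,
    max_k: int = 3,
    max_subset: int = 2,
    max_hidden_sets: int = 500,
) -> MultiplicityVerdict:
    """Screen for multiple Markov boundaries by hide-and-rediscover.

    Hide-sets R (|R| <= max_subset) are drawn from the union of members of
    all boundaries accepted so far, so chains of equivalent variables are
    followed beyond the base boundary.  A rediscovered boundary M' is
    accepted when, for every member b of the base boundary outside M', the
    target tests independent of b given M' (the equivalence criterion,
    judged at the tester's alpha).
    """
    base = discover_markov_boundary(tester, target, max_k)
    if not base:
        return MultiplicityVerdict(unique=True, boundaries=[frozenset()])

    boundaries: list[frozenset] = [base]
    details: list[dict] = []
    tested: set[frozenset] = set()
    n_tested = 0
    grew = True
    while grew and n_tested < max_hidden_sets:
        grew = False
        universe = sorted(set().union(*boundaries))
        hide_sets = []
        for size in range(1, max_subset + 1):
            hide_sets.extend(
                frozenset(c) for c in combinations(universe, size)
            )
        for R in hide_sets:
            if R in tested or n_tested >= max_hidden_sets:
                continue
            tested.add(R)
            n_tested += 1
            sub = tester.restrict(R)
            if target not in sub.variables or len(sub.variables) < 2:
                continue
            alt = discover_markov_boundary(sub, target, max_k)
            if not alt or alt in boundaries:
                continue
            checks = []
            ok = True
            for b in sorted(base - alt):
                res = tester.test(target, b, sorted(alt - {b}))
                checks.append(
                    {"member": b, "p_value": res.p_value,
                     "independent": res.independent}
                )
                if not res.independent:
                    ok = False
                    break
            if ok:
                boundaries.append(alt)
                details.append(
                    {"hidden": sorted(R), "boundary": sorted(alt),
                     "checks": checks}
                )
                grew = True
    return MultiplicityVerdict(
        unique=len(boundaries) == 1,
        boundaries=boundaries,
        hidden_sets_tested=n_tested,
        details=details,
    )
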