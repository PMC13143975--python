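"""Local causal discovery: the parents-and-children set of a target.

Semi-interleaved HITON-PC with bounded conditioning-set size (max-k):
candidates are ranked by marginal association strength, admitted one at a
time, and the tentative set is re-screened after every admission by testing
each member against all subsets of the other members up to size max-k.  A
variable leaves the set the moment a separating subset is found, and that
sepset is recorded for later collider orientation.  An AND-rule symmetry
correction across all per-variable runs removes one-sided memberships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

from .citest import CITester, CITestResult
from .datamodel import ValidationError


@dataclass(frozen=True)
class TraceEntry:
    action: str  # admit | remove | reject_marginal | symmetry_remove
    variable: str
    result: Optional[CITestResult]


@dataclass
class PCSet:
    """Parents-and-children estimate for one target, with its audit trail."""

    target: str
    members: set[str] = field(default_factory=set)
    sepsets: dict[frozenset, frozenset] = field(default_factory=dict)
    trace: list[TraceEntry] = field(default_factory=list)

    def record_sepset(self, other: str, S: Iterable[str]) -> None:
        self.sepsets[frozenset((self.target, other))] = frozenset(S)


def gll_pc(
    tester: CITester,
    target: str,
    max_k: int = 3,
    variables: Optional[Iterable[str]] = None,
) -> PCSet:
    """Estimate the parents-and-children set of ``target``.

    ``variables`` defaults to everything the tester can see.  Independence is
    judged at the tester's alpha; every admission and removal is logged with
    the triggering test result.
    """
    pool = list(variables) if variables is not None else list(tester.variables)
    if target not in pool:
        raise KeyError(f"target {target!r} not among testable variables")
    others = [v for v in pool if v != target]
    if not others:
        raise ValidationError("need at least 2 variables for local discovery")

    pc = PCSet(target=target)
    marginal: dict[str, CITestResult] = {}
    for v in others:
        res = tester.test(target, v, ())
        marginal[v] = res
        if res.independent:
            pc.record_sepset(v, ())
            pc.trace.append(TraceEntry("reject_marginal", v, res))

    # admission order: strongest marginal association first
    candidates = sorted(
        (v for v in others if not marginal[v].independent),
        key=lambda v: (marginal[v].p_value, -abs(marginal[v].statistic), v),
    )

    tentative: list[str] = []  # admission order

    def eliminate() -> bool:
        """One screening pass; returns True if any member was removed."""
        removed = False
        for y in list(tentative):
            found = _find_sepset(tester, target, y, tentative, max_k)
            if found is not None:
                S, res = found
                tentative.remove(y)
                pc.record_sepset(y, S)
                pc.trace.append(TraceEntry("remove", y, res))
                removed = True
        return removed

    for cand in candidates:
        tentative.append(cand)
        pc.trace.append(TraceEntry("admit", cand, marginal[cand]))
        eliminate()

    # final elimination passes to a fixed point
    while eliminate():
        pass

    pc.members = set(tentative)
    return pc


def _find_sepset(tester, target, y, tentative, max_k):
    pool = sorted(v for v in tentative if v != y)
    for size in range(0, min(max_k, len(pool)) + 1):
        for S in combinations(pool, size):
            res = tester.test(target, y, S)
            if res.independent:
                return set(S), res
    return None


def symmetry_correct(
    pcsets: dict[str, PCSet], rule: str = "AND"
) -> dict[str, PCSet]:
    """Resolve one-sided memberships across all local runs.

    AND (default): keep y in PC(x) only when x is also in PC(y) — the
    false-positive-controlling choice.  OR: union the one-sided memberships.
    """
    if rule not in ("AND", "OR"):
        raise ValueError(f"symmetry rule must be AND or OR, got {rule!r}")
    out: dict[str, PCSet] = {}
    for x, pcx in pcsets.items():
        members = set(pcx.members)
        trace = list(pcx.trace)
        for y in sorted(pcx.members):
            if y not in pcsets:
                continue
            mutual = x in pcsets[y].members
            if rule == "AND" and not mutual:
                members.discard(y)
                trace.append(TraceEntry("symmetry_remove", y, None))
        if rule == "OR":
            for y, pcy in pcsets.items():
                if y != x and x in pcy.members:
                    members.add(y)
        out[x] = PCSet(
            target=x, members=members, sepsets=dict(pcx.sepsets), trace=trace
        )
    return out
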