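# Methods

`pcdsp` implements a constraint-based causal discovery pipeline for
observational cohort data in which every variable carries a time *epoque*
(an ordinal measurement period, here 1–8).  The pipeline learns a partially
directed causal network from conditional-independence (CI) tests, reads off
the Markov boundary of a designated outcome, screens that boundary for
multiplicity, scores edge stability by bootstrap, and ranks upstream
variables by a path-based intervention-impact heuristic.  Because the kind
of cohort it targets is typically access-restricted, the package ships a
synthetic generator that reproduces the statistical structure the analysis
assumes, together with an exact d-separation oracle, so every stage is
testable end to end.

## Model and assumptions

The working assumptions are the causal Markov condition and faithfulness:
conditional independencies in the data are exactly those implied by
d-separation on an (unknown) acyclic causal graph over the measured
variables.  Time order is treated as known fact: no causal edge may point
from a later epoque into an earlier one.  Hidden common causes outside the
measured set are not modelled; multiplicity testing (below) screens for the
most common *within-data* faithfulness violation, information-equivalent
variables.

## Conditional-independence testing

The default backend for any mix of binary/ordinal/cardinal variables is
Fisher-z on midrank-transformed columns: each column is replaced by the
midranks of its observed cells (computed once, per column), the partial
correlation r of x and y given S is taken on the rows complete in
{x, y} ∪ S, and the statistic is `sqrt(n_eff − |S| − 3)·|atanh r|` with a
two-sided normal p-value.  Rank transformation buys invariance to monotone
recodings — the natural robustness level for survey-style ordinal data —
at a negligible calibration cost (measured type-I rate 0.044–0.045 at the
nominal 0.05, n = 1000).  A G² log-likelihood-ratio test on stratified
contingency tables is available for all-discrete variable sets
(`method="g2"` or `"auto"`), with df = (levels(x)−1)(levels(y)−1)·Π levels(S)
counted on the complete cases.

Missing data are handled by test-wise deletion: each test uses exactly the
rows complete for its own variable set, with n_eff and df adjusted
accordingly.  This is unbiased under MCAR, which is the only missingness
mechanism the generator produces.  Tests that cannot be computed — fewer
than |S|+4 complete rows, a zero (residual) variance, empty strata — return
the conservative "independent by insufficiency" outcome and are logged on
the tester, never dropped silently.  Zero residual variance is how perfect
collinearity (e.g. a duplicated variable in the conditioning set) surfaces;
treating it as independence is deliberate: a variable carrying no
information beyond the conditioning set should not anchor an edge.

Alpha is fixed at 0.05 with no multiple-testing correction; error control
in this family of algorithms comes from the bounded conditioning-set size
(max-k) and the symmetry correction, not from p-value adjustment.

## Local-to-global discovery

Per variable, a semi-interleaved HITON-PC search estimates the
parents-and-children (PC) set with max-k = 3: candidates are ranked by
marginal association (p ascending, |statistic| descending, name), admitted
one at a time, and after each admission every tentative member is re-tested
against all subsets of the other members up to size max-k, leaving the set
the moment a separating subset is found (the sepset is recorded).  A final
elimination pass runs to a fixed point.  The AND-symmetry rule then removes
one-sided memberships: the edge x–y survives only if each endpoint is in
the other's PC set.  One-sided false admissions among non-adjacent
descendants are an expected feature of interleaved PC search (conditioning
on children can open collider paths), and the AND rule is precisely the
mechanism that eliminates them: on random tiered DAGs with in-degree ≤ 3
the post-correction skeleton equals the true skeleton exactly under the
d-separation oracle.

Orientation proceeds in three phases with strict precedence and per-edge
provenance:

1. **temporal** — every cross-epoque edge points forward in time;
2. **collider** — unshielded triples A—C—B with C ∉ sepset(A, B) become
   A→C←B, unless an arm would oppose an existing orientation, the epoque
   order, or acyclicity (skipped and logged);
3. **meek** — Meek rules R1–R4 propagate to a fixed point.

Iteration order is lexicographic everywhere, so identical inputs give
byte-identical outputs.  On graphs small enough to enumerate, the resulting
orientations equal the consensus of all DAG extensions consistent with
skeleton + tiers + sepsets (verified exhaustively in the test suite), i.e.
the pipeline orients exactly the compelled edges.

## Markov boundary and multiplicity

From a learned graph, the boundary of a target is read off as direct causes
(parents) ∪ direct effects (children) ∪ spouses (other parents of children),
with undirected neighbours included as a flagged, conservative extra set.
Directly from data, `discover_markov_boundary` runs HITON-MB-style: the
symmetric PC set, then spouse recovery via the collider signature (x,
adjacent to a member y, re-activates against the target when y joins x's
sepset), then a backward pass that re-tests every admitted spouse given the
rest of the boundary.  The backward pass serves two purposes: it removes
candidates admitted through longer collider chains, and under information
equivalence it keeps exactly one representative of a duplicated pair —
a strict symmetry filter would instead delete both copies, because perfect
collinearity makes every adjacency of a copy "separable" through its twin.

Multiplicity — several distinct Markov boundaries for one target, the
signature of information-equivalent variables — is screened TIE*-style:
hide subsets (size ≤ 2 by default) of already-discovered boundary members,
re-run boundary discovery on the reduced variable set, and accept an
alternative boundary M′ when the target tests independent of every base
member outside M′ given M′.  Hide-sets are drawn from the union of members
of all boundaries found so far, so chains of equivalent variables (three-way
copies and beyond) are followed; the search is capped (500 hide-sets) for
runtime.  The equivalence criterion, depth, and cap are explicit parameters:
the original TIE* leaves these open, and different instantiations trade
sensitivity for cost.

## Stability and impact

Edge stability is the percentage of B = 100 bootstrap resamples (rows drawn
with replacement, full pipeline re-run) in which an adjacency is detected,
orientation-agnostic by default since orientation provenance varies across
resamples.  Replicates draw from independent substreams spawned from the
master seed, so replicate b is identical regardless of B or execution
order.  Detection percentages are conditional on the observed sample: a
truly null pair whose empirical correlation happens to sit near the
rejection threshold can be "detected" in many replicates of that same
sample, so null-pair stability is bounded in expectation (mean ≈ 15% over
seeds in our checks) but not per draw.

Intervention impact is a path-counting heuristic: enumerate all directed
simple paths of 1..4 edges terminating at the target (undirected edges
excluded by default — traversing them would count non-causal routes), then
score each upstream node by the fraction of paths that vanish when the node
and its incident edges are deleted.  "Path length" is counted in edges; the
cap and undirected-traversal behaviour are configurable.  Enumeration is
exact, not sampled.

## Synthetic generator

`sample_model` assigns variables uniformly to epoques, samples edges only
in epoque-nondecreasing direction (same-epoque ties broken by a fixed node
order, keeping the graph acyclic by construction) with a configurable
per-pair probability and optional in-degree cap, and draws weights uniform
on ±[0.3, 1.0] so faithfulness holds away from cancellations.
`sample_data` propagates linear-Gaussian structural equations in
topological order; binary/ordinal variables are produced by monotone
quantile discretization of the node's response, and children consume the
*observed* (discretized) parent codes, so the conditional-independence
structure of the generated data matches d-separation on the DAG exactly.
Duplicate columns (for multiplicity experiments) are exact copies computed
after generation and sit outside the DAG.  MCAR masking is applied
uniformly per cell.

Default study-scale conditions mirror the motivating cohort: 1,053 rows,
252 variables, 8 epoques, edge density tuned to ≈ 6.5 adjacencies per node,
5% missingness, and a binary/ordinal/cardinal mix of 20/30/50%.  The
analysis scripts and the acceptance script run a scaled cohort of 40
variables at ≈ 4 adjacencies per node (in-degree ≤ 3, matching the max-k = 3
identifiability regime) so the full pipeline, including the 100-replicate
bootstrap, completes in minutes on one CPU; skeleton F1 at that scale is
≈ 0.9.  What the generator does *not* emulate: nonlinear mechanisms,
MAR/MNAR missingness, latent confounders, and the measurement properties of
real psychometric instruments — so passing tests certify the algorithmic
machinery under the model's assumptions, not robustness to their violation
on real data.

## Numerical choices and degenerate inputs

* |r| is clipped at 1 − 1e−16 before atanh; exact duplicates still yield
  p = 0 (dependent), while zero *residual* variance (relative tolerance
  1e−10) routes to the insufficiency path.
* Singular conditioning covariance falls back to a least-squares solve.
* Sepset retention: the first (smallest, lexicographically earliest)
  separating set found is stored and used for collider orientation.
* Orientation conflicts are resolved first-come in lexicographic order and
  logged with rule, edge and resolution; nothing is overwritten.
* Empty graphs, isolated targets, zero paths, and empty boundaries are
  well-defined outcomes (warning, empty ranking, vacuously unique verdict),
  not errors.

## Known limitations

Orientation is identifiable only up to the tiered Markov equivalence
class; same-epoque edges not compelled by colliders or propagation stay
undirected.  PC-style discovery with max-k = 3 cannot separate pairs whose
minimal separating sets exceed size 3, so very dense neighbourhoods yield
extra edges.  The multiplicity screen is a bounded search, not a complete
enumeration of the equivalence classes the full TIE* generator explores.
Bootstrap stability under-estimates replicability for weak true effects at
modest n, and the impact ranking is a topological heuristic, not an
estimate of interventional effect size.
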