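# Methods

## Model

`polynet` represents a pharmacological system as a directed tripartite
graph with three node layers — drugs, biological functions (GO terms),
and adverse drug reactions — and two edge layers: drug→GO ("the drug
may significantly perturb this function") and GO→ADR ("perturbation of
this function may manifest this reaction"). The graph is acyclic by
construction and every maximal directed path has length two; each path
is one candidate mechanism for a drug-induced reaction. Edges carry
non-negative weights defaulting to 1.0, i.e. the network is binary
unless the user supplies quantitative perturbation/activity values.

The model is deliberately mechanistic-agnostic: it asserts only
*possibility* relations mined from high-throughput perturbation screens
and association studies. Nothing in it implies that a path's reaction
will occur, and all combination metrics are relative-risk proxies for
hypothesis generation, not calibrated probabilities.

### Combination analysis

For a drug set D the *combination subgraph* is the union of directed
second-order neighbourhoods of the drugs: D, every GO successor of D,
every ADR successor of those GO terms, and only the edges on those
paths. Within it:

* an ADR is **composite** (cADR) when its drug-source set — drugs of D
  with a directed path to it — has size ≥ 2;
* a GO parent g of an ADR is **mode 1** when ≥ 2 drugs of D perturb g,
  and **mode 2** when exactly one drug perturbs g while the ADR's other
  parents contribute at least one different drug. For a composite ADR
  these two classes provably partition its GO parents (any
  single-drug parent of a multi-drug ADR must have a differently
  sourced co-parent), which yields the invariant
  `mode1 + mode2 = number of cADR-adjacent GO nodes` checked
  throughout the test suite;
* **composite risk modules** (CRMs) are connected components of the
  undirected graph over cADRs and their GO parents after removing drug
  nodes. Components are computed over cADRs (not all ADRs) by default
  because module counts then decompose consistently with the cADR count
  (each cADR belongs to exactly one module); an `all_adrs` option gives
  the broader reading. Direction is ignored because modules are
  association sets, not causal paths.

### Activity scores

Activity(a) = Σ_g Activity(a|g) · Σ_{d∈D(g)} Perturbation(g|d), summing
over the GO parents g of the reaction inside the combination subgraph.
The two pure configurations are special cases: a single shared pathway
gives Activity(a|P)·Σ_d Perturbation(P|d) (mode 1) and disjoint
per-drug pathways give Σ_i Activity(a|P_i)·Perturbation(P_i|d_i)
(mode 2). Weights can be overridden per edge without rebuilding the
network; absent keys fall back to stored edge weights, so the default
score is the distinct drug→GO→ADR path count. Activities are reported
raw — the model defines no normalisation across reactions — and are
linear in the perturbation weights and additive over drug subsets with
disjoint GO parents.

## ABC selection of perturbed GO terms

Per drug, significance values are transformed to importances
(p-values via −log₁₀ p, p = 0 clipped to the smallest positive float
with a warning; pre-computed importances pass through) and ranked
descending, ties broken by GO identifier for reproducibility. The
cumulative curve uses the discrete per-item points x_i = i/n,
y_i = cumulative share — no interpolation, so boundaries are exactly
testable against exhaustive search. Set A ends at the curve point
nearest (0, 1) (smallest rank wins distance ties); set B ends at the
last rank whose discrete slope n·imp_i/total ≥ 1, forced up to the A|B
boundary when smaller. Edges are built from set A only. Alternative
selectors (top-k, p-threshold) plug into the same builder interface for
sensitivity analysis.

Two behavioural notes, confirmed by brute-force boundary search:

* the nearest-point rule can admit a few background items into A when a
  strong signal sits over a flat weak background (the second curve
  point may be marginally closer to (0,1) than the first), and can stop
  just short of the last of several equal-strength signals;
* exact recovery of a planted signal set requires the signal to carry
  the dominant share of total importance mass. With 50 GO terms, a 20 %
  signal fraction and signal p-values at least four orders of magnitude
  below the 0.05 background floor, the boundary-step inequality
  (2k+1)/n² > 2·B·b₁/T² holds with a large margin and recovery is exact;
  with one or two signal terms it is not, because the background mass
  dominates the cumulative curve regardless of separation.

## Network assembly and pruning

The drug→GO layer (one edge per selected term; weight 1.0 or the
importance under the `importance` weight policy) is merged with the
externally supplied GO→ADR association layer. Identifiers are matched
as case-preserved strings (case-insensitive collision errors, no
ontology-aware mapping); parallel edges collapse by weight summation
with a warning. Pruning removes GO terms lacking either an incoming
drug edge or an outgoing ADR edge — they lie on no drug→reaction path —
and then drugs/ADRs left isolated. The cascade to outer layers keeps
reported layer counts consistent with the path semantics; pruning is
idempotent and the result passes strict validation (every GO node has
both neighbours, no isolated outer nodes).

## Pairwise screens and clustering

Each unordered pair of a drug panel is analysed as a two-drug
combination; the chosen metric (cADR count, mode-1/mode-2 GO node
count, or CRM count) fills a symmetric integer matrix with a zero
diagonal (composite concepts are undefined for a single drug). Row
order comes from agglomerative clustering — Euclidean distance, average
linkage by default, both configurable — via
`scipy.cluster.hierarchy`; the permutation is stored with the matrix
and written into the CSV export so orderings are auditable. An
all-equal-rows matrix short-circuits to the identity permutation with a
warning. Combinations of three or more drugs are exposed as a lazy
iterator rather than materialised arrays because the combination count
grows combinatorially.

## Synthetic data

The generator draws both bipartite layers as independent Bernoulli
edges — default densities 0.23 (drug→GO) and 0.012 (GO→ADR), the
densities implied by the published full network's layer sizes — at a
default CI-friendly scale of 100 drugs × 50 GO terms × 30 ADRs
(full-study scale is just larger size parameters). Planted modules are
complete drug×GO and GO×ADR blocks on disjoint index ranges. Ground
truth accompanies every draw: planted memberships, and the exact
expected risk-module structure of the all-planted-drugs combination,
recomputed by a union-find component search directly on the boolean
adjacency matrices, independent of the analysis code path. A single
`numpy.random.Generator` (PCG64) stream seeded from `cfg.seed` drives
everything, so one seed reproduces outputs byte-for-byte (reproducible
across platforms to the extent the generator algorithm is, which the
truth record names).

Perturbation tables give each drug a signal GO subset — default size
20 % of the vocabulary, matching the per-drug selected fraction implied
by the published network's edge counts (~75 of 323 terms) — with
p-values log-uniform over [1e-12, 1e-4] against a uniform(0.05, 1)
background.

What the generator does *not* emulate: correlated GO terms (real
perturbation signatures are strongly collinear), heavy-tailed per-drug
degree distributions, shared mechanisms between chemically similar
drugs, and any dependence between the two layers. Passing tests
therefore demonstrate algorithmic correctness on independent-edge
graphs, not performance on real pharmacological networks.

A planted-structure caveat found during validation: with complete
planted modules, a single background drug→GO edge from a foreign drug
into a module's GO block makes that drug reach the module's entire ADR
block, shifting its whole pairwise-cADR row by the module size. Planted
*block recovery* by clustering is therefore only well-posed when
cross-module drug→GO background is absent; the recovery checks
accordingly use zero drug→GO background (GO→ADR background is benign —
it only adds within-module composites) so that block separation is
guaranteed by construction rather than by chance.

## Numerical and degenerate-input choices

* All tie-breaks (importance ranking, ABC boundary distance ties,
  module ordering) resolve by ascending identifier, making every output
  deterministic for a given input.
* "No signal" rows (all p = 1, or all values missing) raise an error
  per drug; the network builder collects such drugs, warns, and
  continues.
* Empty networks, empty drug sets and reactions with zero paths are
  legal inputs returning empty/zero results, not errors.
* GML output orders nodes drugs-first, then GO, then ADRs, each block
  lexicographic, so files are byte-reproducible; GML input tolerates
  unknown attributes and infers missing layer labels structurally
  (sources = drugs, sinks = ADRs, interior = GO) with a warning.
* The published formulation of the worked blurred-vision expansion
  contains a mismatched GO identifier in its final term; the
  implementation follows the consistent general summation form above.

## Problem sizes used in the automated checks

The dual-route (implementation vs brute-force enumeration) batteries
use 200 random networks of at most 50 nodes; ABC boundary agreement is
checked on instances up to n = 200 items; monotonicity on 50 networks
with nested drug sets; the screen check on a 20-drug panel with two
planted 10-drug modules. These sizes make every property exhaustively
checkable by the oracles while exercising all code paths; full-scale
networks (thousands of drugs) run through the same code, and the
reference-network test in the acceptance suite applies it to a
published full-scale GML when that file is supplied locally.

## Known limitations

* Binary "may perturb"/"may manifest" semantics; no edge confidences
  unless supplied by the user.
* No statistical significance testing of cADR counts, no clinical
  severity weighting, and no calibration of activity scores against
  pharmacovigilance incidence data.
* GO vocabulary matching is exact-string; no ontology traversal or
  term collapsing.
* The ABC selector's set A is a mass-concentration construct: it is not
  a hypothesis test, and its size depends on the global shape of the
  importance distribution, not on a significance threshold.
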