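# Methods

This note documents the models and procedures implemented in
`weavenet`, the parameters that matter, the numerical choices, and the
limitations of the synthetic study design.

## The mixed graph and ontology model

An organism is represented as a graph with two node types (proteins,
GO terms) and three edge types: undirected physical interactions,
directed regulatory interactions (TF → target), and protein–term
annotation edges. Physical and regulatory edges between the same
protein pair are parallel edges, never merged — collapsing them would
make a mixed feedback loop indistinguishable from a feed-forward loop.
Physical self-loops are dropped; regulatory self-loops (autoregulation)
are retained in the edge set but ignored by path queries and the motif
census, which are defined on distinct node triples. Protein identifiers
are matched case-insensitively and reported in first-seen form, since
real corpora mix gene symbols and locus ids.

Annotations follow the true-path rule: `propagate_annotations`
materializes an *inferred* record for every ancestor (via `is_a` and
`part_of`; the traversed relation set is configurable, and
regulates-type relations are never traversed) of every direct record.
A (protein, ancestor) pair that is itself directly annotated stays
direct. The ontology roots — the three GO namespace roots and, in
synthetic ontologies, any term without parents — are excluded from
inference: every protein would otherwise be annotated to them, which
destroys the specificity of term-based ranking. Propagation is
idempotent, and obsolete terms are dropped from annotation ingest with
logged counts. The only annotation filter applied at ingest is removal
of NOT-qualified GAF records; evidence-code policies are deliberately
out of scope.

## Subnetwork queries

Both query modes connect a source protein *s* to the proteins
annotated (directly or by inference) to a term *t*, over a
physical-only, regulatory-only, or mixed edge filter. Regulatory edges
are traversed as undirected during search — subnetwork extraction asks
"what connects these proteins", not "what is downstream" — but retain
their true direction in the output.

**k unique paths** returns the k globally shortest simple paths from
*s* to *any* member of the target set, by edge count. It is
implemented as a lazy best-first enumeration of simple paths ordered by
the pair (length, node-id sequence): partial paths are expanded in a
priority queue, so completed paths arrive in globally sorted order.
This is output-equivalent to Yen's algorithm run against the target
set, with two properties Yen implementations do not generally provide:
fully deterministic lexicographic tie-breaking, and prefix stability
(the first k paths of a k′ > k query equal the k-query's result).
Several paths may share a terminal node; paths may pass through
annotated proteins as intermediates; a source annotated to its own
query term is excluded from the target set so paths lead to *other*
members. Paths are node sequences: two routes differing only in which
parallel edge (physical vs regulatory) they use are one path, and the
output edge list carries every parallel edge along the route.

**k unique nodes** breadth-first-searches from *s*, selects up to k
annotated proteins by (shortest-path distance, node id), and attaches
one witness path per selected node — the lexicographically smallest
shortest path — so the subnetwork stays connected to the query protein.

Worst case, best-first simple-path enumeration is exponential; a
configurable expansion cap (default 2×10⁶) turns pathological queries
into a clear error rather than a hang. In the intended regime (small
k, targets within a few hops) it is fast.

## Motif census and enrichment

Five 3-node classes are counted. On an induced triple with physical
pair set P and regulatory arc set R (each direction of a reciprocal
pair considered separately):

- protein clique — all three pairs in P;
- feed-forward loop (FFL) — some role assignment has X→Y, X→Z, Y→Z in
  R, and no such assignment has the TF pair {X,Y} in P;
- mixed feedback loop (MFL) — an FFL role assignment whose TF pair is
  in P;
- interacting coregulators — {X,Y} in P, X→Z and Y→Z in R;
- coregulated interactors — X→Y, X→Z in R and {Y,Z} in P.

Two structural decisions were genuinely open. First, the protein-clique
pattern is tallied independently of the regulatory/mixed patterns, so a
triple can count as a clique *and* one regulatory class; in
interactomes where dense physical complexes are also co-regulated,
exclusive counting would hide the clique signal that dominates most
species' backgrounds. Second, among the regulatory/mixed patterns at
most one class is assigned per triple, by precedence MFL > FFL >
interacting coregulators > coregulated interactors: the MFL/FFL
ordering is forced by the definition (an MFL *is* an FFL plus a TF–TF
interaction, and must not be double-reported), and the remainder of the
order resolves rarer overlaps deterministically, most-constrained
pattern first.

Every class requires all three pairs to be adjacent in the undirected
union of the two edge sets, so the census enumerates union-triangles
(edge-pivoted, sorted-order) and classifies each — provably equal to
O(n³) triple enumeration, which the test suite checks exhaustively.

Enrichment compares a subnetwork's counts to a null of `reps` random
connected induced subgraphs with the same node count, snowball-sampled
(uniform frontier growth from a random start) from the background
graph. Connectivity-matching reflects that queried subnetworks are
connected by construction; a degree-preserving edge-swap null is a
possible extension, not implemented. Per class: Z = (obs − mean)/sd
with the sample sd (Z undefined and reported as null when sd = 0 and
obs ≠ mean; 0 when the null is degenerate at the observation),
enrichment ratio obs/mean (null when the mean is 0), and empirical
p = (1 + #{null ≥ obs})/(reps + 1) — the +1 correction keeps p > 0 at
finite reps. Defaults: reps = 199 in the CLI (a p-resolution of 0.005,
cheap enough for interactive use); both reps and seed are recorded in
the report.

## Annotation scoring

**RandomWalk.** Personalized PageRank on an undirected walk substrate:
p = (1−α)·r + α·Wᵀp, with r uniform over the proteins annotated
(directly or by inference) to the term and W the column-normalized
adjacency. Solved by power iteration with an L1 stopping tolerance
(default 1e-10, cap 1000 iterations, error with residual on
non-convergence); mass at degree-zero nodes is redistributed to the
restart vector, so Σp = 1 holds to 1e-9 throughout. α = 0.7 under the
convention that α multiplies the walk term — the walk follows an edge
with probability 0.7 and restarts with probability 0.3. The default
walk universe (`full`) is the composite graph: proteins, interaction
edges (both types, undirected, uniform transition probabilities),
GO-term nodes, direct *and* inferred annotation edges, and the GO
hierarchy's term–term edges. Two ablation universes —
`interactions_only` and `annotations_only` — drop the annotation side
or the interaction side respectively.

**Comparators.** Degree ranks the query by its mixed degree and ignores
the term entirely (a degree-bias control). One-Hop counts the query's
neighbors annotated to the term. Hypergeometric scores the upper-tail
probability P[X ≥ x] of observing x annotated neighbors when deg(s)
neighbors are drawn from N proteins of which K are annotated (smaller
is better). Ranks are competition ranks (ties share the best rank),
with lexicographic protein id as the final deterministic key.

## Evaluation harness

Positives are direct (protein, term) records drawn uniformly without
replacement. For each trial, the positive's direct record is removed
from a copy of the annotation set, together with any inferred ancestor
records that lose their last direct support from that protein —
inferred edges exist only by virtue of direct evidence below them.

Negatives per positive: up to m proteins that (1) lie within a hop
radius of the positive on the interactions-only view (default 2,
relaxed stepwise to 4 when the pool is short, with the relaxation
recorded), (2) are *not* annotated to the term, directly or by
inference — this criterion is never relaxed — and (3) match the
positive's mixed degree within max(2, 10% of the positive's degree).
Positives with an empty pool after full relaxation are skipped and
logged.

Scores from different trials are not commensurable (terms differ in
size and topology), so pooling converts each trial's scores to
within-trial normalized competition ranks, 1 − rank/(1 + candidates),
before concatenation; raw-score pooling is available as an option. ROC
curves and trapezoidal ROC AUC, and precision–recall curves with
step-interpolated PR AUC (average precision), are computed with
scikit-learn from the pooled table.

## The synthetic generator and the study conditions

`make_mixed_graph` emulates the structure that makes
guilt-by-association work: functional modules that are both *physically
cohesive* and *co-annotated*.

- 600 proteins; background PPI edges Erdős–Rényi with p = 0.05 (mean
  physical degree ≈ 30, comparable to the dense yeast/fly interactomes
  at desk scale).
- 20 disjoint modules of 25 members, each tied to a leaf term of a
  depth-2, branching-7 synthetic ontology; within-module edge
  probability = 3 × background.
- Each module also has one *companion* leaf term; members are annotated
  to their module term and companion term independently with
  probability 0.8 (the annotation completeness). Companion terms model
  the correlated multi-term annotation profiles of real proteins —
  members of one process share several related annotations, and this
  co-annotation channel is a large part of what the full-universe walk
  exploits. One companion per module is a conservative floor: real
  corpora carry tens of annotations per protein.
- The 20% of members left unannotated are recorded as hidden ground
  truth — the recoverable targets for the ranker.
- 10% of proteins are TFs; 600 regulatory edges drawn TF → random
  target, plus 3 planted TF → member edges per module so mixed queries
  have regulatory structure to traverse.

Everything is deterministic in the seed, and fixtures serialize to the
same TSV/OBO/GAF dialects the parsers read, so generator and parsers
test each other.

What the generator does *not* model: heavy-tailed degree distributions
and hubs, overlapping module membership, annotation depth (real
proteins are annotated at many ontology levels), evidence-code
structure, and assortativity. Benchmark results on these fixtures
therefore demonstrate that the implementation ranks correctly when
module structure is present at a known strength — they are not
estimates of performance on any real species. In particular, hidden
module members are legitimately eligible as negatives (they satisfy the
"not annotated" criterion), exactly as unannotated true members
contaminate any real-data benchmark; they act as hard negatives and
bound the attainable AUC below 1.

At these study conditions the RandomWalk's pooled ROC AUC per seed is
distributed around 0.90 (typically ±0.03 seed to seed at 50 trials),
and it exceeds all three comparators in every seed we have run, with
Degree at chance level against degree-matched negatives — the expected
ordering when multi-hop and co-annotation signal is informative.

## Problem sizes

The test suite and acceptance script scale the designs to sizes chosen
for a single CPU: oracle comparisons use hundreds of random graphs of
≤ 15 nodes (where exhaustive enumeration is exact and fast); the
benchmark uses 5 fixture seeds × 50 positives × 50 negatives on the
600-protein fixture; motif nulls use 199 replicates. These sizes are
the package's defaults for its own validation, not statements about the
limits of the methods.
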