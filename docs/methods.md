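# Methods

## Problem setting

Given (i) an undirected, unweighted protein–protein interaction network,
(ii) a rooted ontology DAG (single namespace, `is_a`/`part_of`
parent relations), (iii) a protein→term annotation corpus and (iv) a
query protein set, the pipeline answers two questions per term: is the
term's annotated protein set overrepresented in the query (standard
enrichment), and is the term's *network module* overrepresented in the
query (network enrichment)?  The second can return terms carried by no
query protein, because modules recruit connecting proteins by network
position rather than annotation.

## Annotation model

Annotations propagate upward: a protein directly annotated with *t* is
implicitly annotated with every ancestor of *t* along `is_a` and
`part_of` edges.  `regulates`-type relations are ignored, matching the
propagation convention of protein-centric GO corpora.  Obsolete terms
are dropped at parse time; `alt_id` aliases resolve to primary ids;
GAF rows carrying the `NOT` qualifier are excluded.  Term frequency,
information content and enrichment backgrounds are all computed on the
propagated corpus; terms annotating zero proteins have undefined
information content and are excluded from similarity computations and
backgrounds.

Information content uses the natural logarithm,
`IC(t) = −ln(|proteins(t)| / |annotated proteins|)`.  Only IC ratios
enter Lin's score, so the base cancels; it is fixed for
reproducibility.  Lin similarity takes the most informative common
ancestor over the two terms' ancestor closures *including the terms
themselves* (the standard convention), returns 0 when the MICA is
uninformative (IC = 0) or when the terms share no ancestor, and is
symmetric by construction.

A protein's *maximum semantic similarity* to a reference term is the
best Lin score over its **direct** terms (configurable to the
propagated closure; ancestors can only dilute the maximum since each
ancestor's similarity is bounded by its descendant's).  Unannotated
proteins score 0 rather than being excluded: connecting nodes are often
unannotated and must still be rankable.

## Module extraction

Seeds are the proteins *directly* annotated with the reference term —
propagation is deliberately not used here, so each module reflects the
term's own annotation signal, not its descendants'.  Seeds missing from
the network are carried as isolated, degree-0 members throughout.

The shortest path network (SPN) is the union of all shortest paths
between in-network seed pairs: node *v* enters iff
`d(s,v) + d(v,t) = d(s,t)` for some pair, and an edge `(u,v)` enters
iff it lies on such a path (`d(s,u) + 1 + d(v,t) = d(s,t)` in either
orientation).  Only path edges are kept, not the induced subgraph.
Seed pairs in different components impose no constraint anywhere.

Minimization deletes connecting nodes greedily, least important first,
keeping a node whenever its deletion would change any connected seed
pair's distance from its original full-network value.  Three choices
deserve emphasis:

* **Distances are always checked against the full network**, cached
  once per term.  Re-checking against the shrinking SPN would let
  distances drift upward silently across deletions.
* **Removal order** is the ascending lexicographic triple
  (`sc`, `ss`, `bc`), with ties broken by ascending node identifier.
  The optimal distance-preserving subgraph is usually not unique; the
  deterministic tie-break makes outputs byte-reproducible.
* **Seed-pair betweenness** counts, for each seed pair, the fraction of
  that pair's shortest paths passing through the node (endpoints
  excluded — immaterial, as seeds are never removal candidates).

The greedy result is 1-minimal: deletions only shrink the path set, so
a node kept at its turn can never become removable later.  Exact
minimality is not attempted (the problem is Steiner-tree-like); an
exhaustive optimum is computed only as a test oracle on ≤ 12-node
instances, where the greedy heuristic attains the optimum on every
sampled instance (mean size ratio 1.0).

**Quality filtering.**  Modules without connecting nodes are trivial
and rejected.  Modules with exactly one connecting node are rejected
too, because the within-group variance of the similarity test is then
undefined; this is logged as its own category.  Otherwise the module is
accepted iff a one-sided Welch (unequal-variance) two-sample t-test
finds the connecting nodes' mean maximum semantic similarity to the
reference term significantly above the mean over all network nodes at
α = 0.05.  Terms with fewer than two in-network seeds are recorded as
`too_few_seeds` without building: no seed pair exists, so the module
could only be trivial.

## Enrichment

Both tests are one-sided Fisher exact tests computed as exact
hypergeometric tail sums in integer arithmetic (relative error at float
precision; validated exhaustively against an independent survival
function for all N ≤ 60).

* Standard: universe = all annotated proteins; positives for a term =
  its propagated annotation set.
* Network: universe = union of all accepted module member sets
  (in-network seeds + retained connecting nodes + isolated seeds);
  positives = the term's module members.

Only terms overlapping the query are tested; the Bonferroni factor
defaults to the number of tested terms and can be switched to the full
background term count (`--bonferroni universe`), which is strictly more
conservative.  Query proteins outside the universe are dropped from
*n* and reported in the log.  Results at corrected p ≤ α are sorted by
corrected then raw p-value, then term id.

"Non-redundant ranking" is implemented as ancestor deduplication: a
result whose term is a strict ancestor of another reported term is
removed (most-specific-term rule); when comparing network against
standard results, network terms that are ancestors of standard hits are
likewise discounted.  A network hit is an *added-value* (`is_new_term`)
term when it is absent from the propagated annotations of every query
protein — the strictest notion of novelty; comparing against direct
annotations would inflate novelty counts.

Outcome classes for a standard/network comparison, in precedence
order: nothing significant anywhere → `none_significant`; any added
network term absent from the query's propagated annotations →
`net_new_terms`; any other added network term →
`net_more_known_terms`; otherwise `same_terms`.

## Synthetic fixtures

The generator emulates the pipeline's inputs at desk scale and plants
modules whose recovery is provable, not probabilistic:

* Background graph: Erdős–Rényi G(300, 0.02) by default (mean degree
  ≈ 6), or preferential attachment.  The toy scale keeps exhaustive
  oracles tractable; no attempt is made to fit real interactome degree
  distributions.
* Ontology: a complete `is_a` tree (depth 3, branching 3 by default).
  Each planted module owns one leaf-parent branch: seeds carry the
  first leaf (the planted term), connectors carry the sibling leaf, so
  connector similarity to the planted term is high through the shared
  parent.
* Planted topology: 8 seeds and 4 connectors per module by default
  (12 members).  Connectors are wired as bridges between consecutive
  seeds, and any competing direct edge or second common neighbour is
  cut, so each bridged pair's geodesic is *unique* and the connector is
  provably in the SPN and unremovable.  Non-consecutive seeds are
  interconnected with probability 0.65: functional modules are densely
  wired in real interactomes, and the density keeps within-module
  geodesics competitive with background shortcuts so minimization can
  discard unrelated background nodes (a sparsely wired "module" is not
  a module — its connecting neighbourhood fails the similarity test, as
  the quality filter intends).
* Corpus: ~10 % of background nodes get a noise annotation from leaves
  outside the planted branches; each related term additionally
  annotates 10 off-network padding proteins (annotated proteins absent
  from the interactome, as in real corpora — this also gives the
  connector-seeded sibling modules a larger membership than the planted
  modules, mirroring the asymmetry between a rare specific term and its
  more common sibling); a few off-network filler proteins carry
  unrelated leaves so that no branch ancestor annotates the entire
  corpus (its IC would collapse to zero, which no real corpus does).
* All randomness derives from the single spec seed through named
  substreams; queries take an independent seed.  Fixtures are rendered
  to the production text formats and re-parsed through the production
  loaders, so I/O paths are exercised by construction.

What passing on these fixtures does **not** show: performance at
interactome scale (10⁴ nodes, 10⁵ edges), robustness to the degree
bias of scale-free networks, or behaviour under incomplete and biased
real annotation corpora.  The fixtures establish correctness of the
algorithms, not field performance.

## Numerical and degenerate-input choices

* Fisher tails: exact integer/`Fraction` arithmetic; no asymptotics.
* Welch t-test: a zero-variance connecting-node group is fine (the
  network-side variance drives the test); a NaN p-value (both groups
  degenerate) rejects the module.
* Self-loop rows are dropped at network load; a node appearing only in
  self-loop rows is dropped entirely.  Ambiguous identifier mappings
  (one-to-many in either direction) are dropped.
* Empty corpora, empty edge lists, terms without direct annotations,
  queries outside the universe: all produce explicit errors or warned
  empty results, never silent wrong answers.
* Determinism: no wall-clock metadata is written; all collections are
  sorted before serialization; identical inputs and configuration give
  byte-identical module archives and result tables.

## Problem sizes used in the checks

Oracle comparisons run on ≥ 100–200 random instances of ≤ 12 nodes
(≤ 20 terms for the ontology oracles), where exhaustive enumeration is
exact.  Recovery and false-positive rates use the default 300-node
fixture: 100 replicates with 5-member queries for recovery, 200
replicates with 5-decoy pure-noise queries for the false-positive
rate.  These sizes make the full verification suite run in well under a
minute while keeping every estimate at a usable precision.
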