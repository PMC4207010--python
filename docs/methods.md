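# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic data emulate, and the
numerical and design choices made where the design was genuinely open.

## Network consolidation and identifier mapping

Interaction networks are undirected simple graphs over gene identifiers.
Self-loops are dropped and duplicate rows collapsed at read time, so
every downstream stage sees a simple graph; the parse report records how
many rows, loops and duplicates were seen. Merging networks is a plain
union of node and edge sets — when the same interaction is reported by
several source databases with conflicting evidence, no arbitration is
attempted. Namespaces (e.g. `ensembl_gene`, `unigene_rat`) are carried
as metadata and checked for consistency at merge/consolidate time, but
never validated against an external registry.

Ortholog/identifier maps are many-to-many. The default policy is
`expand`: a source gene with *k* targets contributes *k* nodes, and
every edge is re-wired to all target combinations, then simplified (an
edge whose endpoints map to the same target collapses to a dropped
self-loop). `expand` preserves signal at the cost of inflating
ambiguous families; `drop_ambiguous` (keep only 1:1 sources) is
available where strictness matters. Degree-zero nodes are not
representable in the two-column edge-list format; GraphML round-trips
them.

## Signature consolidation and consensus

Consolidation is the union of member signatures with per-gene source
labels, so reports can distinguish omics-derived, literature-derived and
shared features. The consensus of a drug-signature family keeps genes
supported by at least `min_support` members; the default of 2 encodes
the requirement that a feature be replicated in at least two independent
signatures of the same drug class before it is attributed to the class
mechanism rather than to a single compound. Consensus is antitone in
`min_support`, and `min_support=1` degenerates to the plain union.

## Process models

A molecular process model is built in three steps:

1. **Mapping / induced subgraph.** The signature is intersected with the
   network's node set; the induced subgraph keeps exactly the edges with
   both endpoints in the signature. Degree-zero nodes (signature genes
   with no interaction to any other signature gene) are removed before
   segmentation. The report separates *mapped* (present in the network),
   *isolates* and *retained* counts.

2. **MCODE segmentation.** Implemented from scratch following Bader &
   Hogue's description. Scoring: vertices below the degree cutoff score
   0; otherwise the graph induced on the closed neighborhood N[v] is
   reduced to its highest k-core K (the non-empty core with maximal k)
   and score(v) = k · 2|E(K)|/(|K|(|K|−1)), loops excluded. Complex
   growth seeds on the highest-scoring unassigned vertex and does a
   breadth-first expansion admitting unassigned neighbors whose score is
   at least (1 − VWP) of the seed score, to a maximum depth. Grown
   complexes are discarded unless they contain a k-core at the filter
   level; the haircut reduces a complex to its 2-core (a single
   reduction — the 2-core is already the fixed point of iterated
   pruning). Vertices consumed by a grown complex stay consumed even if
   the complex is later discarded, mirroring the original algorithm's
   visited-marking. Fluff is off by default; when on, it only adds
   *unassigned* border neighbors, so segments remain disjoint.

   Defaults are the canonical MCODE settings: degree cutoff 2, node
   score cutoff (VWP) 0.2, k-core filter 2, max depth 100, haircut on,
   fluff off, fluff density 0.1.

3. **Relations.** See below.

All tie-breaking (seed selection, neighbor iteration, output ordering)
is lexicographic on the gene identifier, which makes the segmentation a
pure function of the graph: permuting the input row order cannot change
the result.

**A property worth knowing.** The growth criterion is a *weight*
threshold, not a density threshold. When two equally dense regions are
joined by even a single bridge edge, the vertex across the bridge scores
as high as the seed's own neighbors and is admitted, so the complex
spans the bridge: two bridged K4s segment into one 8-vertex complex, not
two. On planted-partition graphs with homogeneous module densities
(e.g. five 12-gene modules at within-module edge probability 0.9 and
between-module probability 0.02, which plants ~29 bridges), the first
few complexes absorb most modules and the adjusted Rand index against
the planted labels averages only ≈ 0.22 over 20 seeds. This is a
faithful property of the algorithm, not an implementation artifact — the
vertex scores themselves are verified exactly against an exhaustive
subset-enumeration oracle. Recovering homogeneous planted modules would
require a density-aware segmenter, which is out of scope (one algorithm,
as named). Segmentation *does* separate modules whose densities differ
enough that the VWP threshold bites (see the heterogeneous-module demo
study), and on disjoint dense modules it recovers them exactly.

## Inter-process relations

The relation strength between two disjoint gene sets is the number of
network edges with one endpoint in each. Significance is assessed
against a size-matched null: `n_perm` draws of two disjoint node sets of
the same sizes, uniform without replacement from a universe, with

    p = (1 + #{null ≥ observed}) / (n_perm + 1)

so p can never be 0 and the test is valid (super-uniform under the
null). The universe defaults to the substrate (the isolate-free induced
subgraph) — the most conservative choice, since segment genes are by
construction better connected than the full network; the full network is
available as an alternative. Defaults: n_perm 999, α 0.05, BH across all
segment pairs. The z-score against the null mean/SD is reported for
description only; the SD can legitimately be 0 (e.g. on complete
graphs), in which case z is undefined and decisions rest on p alone.
Note that dense regions sit *inside* the sampling universe, so the null
has a heavier tail than a sparse-background intuition suggests: null
draws that capture several members of one dense module in both sets
produce large counts. With 999 permutations the smallest attainable p is
0.001.

For the pathway landscape, each pathway pair is scored by shared genes
and by cross-boundary edges computed after excluding the shared genes
from both sides — overlap and boundary-spanning interaction are kept as
two separate criteria, since counting a shared gene's incident edges as
"cross" would conflate them.

## Enrichment

One-sided (enrichment-only) Fisher's exact test: p = P(X ≥ a) for the
hypergeometric distribution with population |universe|, successes
|annotation ∩ universe| and draws |feature set|. The universe is an
explicit argument — network genes by default, all annotated genes as the
alternative — because it changes every p-value; the choice is echoed in
output headers. Annotations with no gene in the universe are skipped
with a warning rather than tested vacuously. The BH step-up adjustment
is implemented in-package (q(i) = min over j ≥ i of p(j)·m/j on the
ascending sort, capped at 1) and cross-checked against
statsmodels' `fdr_bh` in the test suite.

## Interference

Interference intersects drug and disease segments on gene identity only
— interaction structure does not enter. The default minimum overlap is
1, with a hypergeometric p (population: union of both substrates)
reported per pair so users can apply stricter cuts by overlap or by p.
The segment report aggregates per-disease-segment overlap across all its
drug-segment pairs and lists the biomarker/target candidates and
(optionally) enriched pathways the segment holds.

## Synthetic data

The generators emulate the statistical structure of the real inputs —
not their biology:

- **Interactome:** planted-partition graphs (modules with within-module
  edge probability `p_in` over a background with `p_out`). Degree
  distributions are binomial, not the heavy-tailed degrees of real
  interactomes; segment-size distributions on real data will differ.
- **Signatures:** per-module sampling at a coverage fraction plus
  background noise; a cardinality-exact constructor produces set pairs
  with exact sizes and intersections (e.g. 516/414 sharing 49) to
  reproduce printed set algebra.
- **Drug families:** a planted core with per-gene support ≥ 2 plus
  singleton fillers, so the ≥2-consensus provably equals the core; the
  exact mode solves supports from requested per-signature sizes, unique
  totals and core size (e.g. 442+535+526+558+572+519 = 3152 features,
  2058 unique, 661-gene core).
- **Ortholog maps:** per-gene fan-out drawn from a declared {0, 1, ≥2}
  mix.

Every generator is a pure function of (config, seed) via per-generator
named substreams of a single seed. Passing tests on these data shows the
bookkeeping, statistics and algorithmic contracts are right; it does not
certify behavior on scale-free interactomes or noisy real signatures.

Default study conditions (five 12-gene modules, 200-gene background,
p_in 0.9, p_out 0.02, coverage 0.8, noise 0.1, six drug signatures with
a 100-gene core, ortholog fan-out 10% unmapped / 80% one-to-one / 10%
one-to-many) are small enough that every stage runs in seconds while
leaving all stages non-trivial. The demo study in `analysis/` uses
heterogeneous module sizes (14, 12, 10, 8, 6) at p_out 0.005 instead:
with homogeneous modules the weight-threshold growth merges bridged
modules (see above), and a demonstration study should exercise the
multi-segment pathway of every stage. In that demo, no inter-segment
relation exceeds the size-matched null — the honest outcome for modules
connected only by sporadic background edges.

## Degenerate inputs and numerical notes

- Empty networks, empty signatures and signature/network disjointness
  yield empty (not erroneous) models.
- Scores are exact rational arithmetic in floating point (k ≤ 9 and
  small denominators at test scale); oracle agreement is asserted to
  1e-12.
- BH inputs must lie in (0, 1]; a p of exactly 0 is rejected as a
  contract violation (the permutation p cannot be 0 by construction).
- Hypergeometric tails come from scipy (`hypergeom.sf`), which is exact
  for these table sizes.
- All file outputs are sorted, so byte-identical reproduction holds
  across runs and platforms given the same seed.

## Known limitations

- The segmentation merges equally dense bridged modules (discussed
  above); it is the behavior of the named algorithm.
- The permutation null matches set sizes but not degree sequences; a
  configuration-model null is out of scope.
- PSI-MI-TAB parsing is minimal (interactor columns only); evidence
  codes and confidence scores are ignored.
- The edge-list writer drops degree-zero nodes.
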