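# Methods

## Model and assumptions

`pincomplex` treats protein complexes as dense subgraphs of a simple
undirected PIN and learns what "dense enough, in the right way" means from
curated examples. Three assumptions underlie the design:

1. interactions are noisy, and functional (GO) agreement between interactors
   separates genuine edges from false positives;
2. a linear function of subgraph topology statistics is a useful complex
   score — expressive enough to rank candidates, simple enough to be trained
   from a few hundred examples;
3. maximal cliques are good detection seeds: every complex worth reporting
   contains at least a small fully-connected core.

## GO similarity and the weighted network

Annotations are propagated to ancestors through *is_a* and *part_of* before
any similarity is computed; both relations carry annotation transitivity in
standard GO practice. The similarity of an interacting pair is
−|C(p,q)|·log(min_t S(t)/S_max) over the common term set C(p,q); the
minimum is taken over the terms annotating *both* proteins (the common-term
reading; the alternative — all terms of either protein — would let a term
unrelated to the shared function set the specificity). S_max is global over
all three GO namespaces; a per-namespace mode exists but is not the default
because the similarity is used as a single scalar filter.

The logarithm is natural (configurable via `log_base`). On yeast-scale
annotation (thousands of proteins, specific terms annotating tens), shared
specific terms give similarities of several nats, so the 0.9 edge-retention
cutoff discards pairs sharing only generic terms while retaining pairs with
any reasonably specific common annotation. The cutoff applies to the GO
similarity alone, not to similarity + topological weight: the shared-
neighbor count is a confidence bonus for the weighted features, not part of
the false-positive filter. Topological weights are counted on the original,
pre-filter graph — the weighted network is built once, as a fixed input to
detection.

Pairs with an unannotated endpoint score 0 and are therefore filtered. This
is deliberate and conservative: an edge we cannot corroborate functionally
is treated as unreliable.

## Features

Ten features, in a fixed canonical order (`FEATURE_NAMES`): unweighted
density, mean degree, median degree, mean clustering coefficient; weighted
density, mean and maximum weighted degree, mean edge weight, topological
changes T5 and T7. Notes on the non-obvious choices:

- **Weighted density** sums w(u,v) over *ordered* pairs and divides by
  |V|(|V|−1), so each edge counts twice and a uniform-weight-w clique has
  density exactly w. This makes the weighted and unweighted densities
  coincide at unit weights, which the test suite exploits as an invariant.
- **"Median degree"**: the middle order statistic, with the usual average of
  the two middle values at even counts.
- **Topological changes** T1–T7 are all computed, but only T5 and T7 enter
  the vector — the others measurably do not help, and ablation experiments
  rank them at the bottom. The full profile is exposed via
  `topological_changes` for research use.
- **No standardization.** Features enter the model raw; the fitted weight
  magnitudes are then interpretable against raw feature scales, and the
  pipeline's score comparisons are scale-consistent across stages. Nothing
  in the fitting requires standardization because the divergence guard
  adapts the step size.
- Node sets with fewer than two members are an error, not a zero vector: the
  method never scores singletons (seeds are cliques of size ≥ 3), so a
  silent zero would only mask caller bugs.

## Regression model

The scorer is f(x) = ωᵀx with no intercept, fitted by full-batch gradient
descent on L = Σ(yᵢ − ωᵀxᵢ)² from ω = 0. The update applied is the
*descending* direction ω ← ω + 2η Σ(yᵢ − ωᵀxᵢ)xᵢ — the objective is
explicitly minimized, so the sign of the step follows the minimization, and
the implementation is validated against the normal-equations solution on
random well-conditioned problems (relative L2 gap < 1e−4).

η defaults to 1e−4 ("a small positive value") and is halved whenever a step
would increase L, so the recorded loss trace is non-increasing by
construction; if 200 halvings cannot produce a finite non-increasing step, a
convergence error is raised. The default 500 iterations mirrors the
best-performing configuration on real data, where longer training overfits
the score scale without improving ranking. Labels are 0/1/2 for
negatives/intermediates/positives; the intermediate category ("uncertainty"
predictions from another detector) widens the margin between random sets and
true complexes. An optional constant-1 feature can emulate an intercept;
the default stays faithful to f(x) = ωᵀx.

## Detection pipeline

Maximal cliques are enumerated with Bron–Kerbosch-with-pivoting (via
`networkx.find_cliques`); any correct enumerator is behaviorally equivalent,
and this one has proven worst-case behavior on sparse graphs. Pipeline
choices that were genuinely open:

- **Clique-overlap removal uses ≥ threshold** (2 shared nodes for
  clique size ≥ 3, 3 for ≥ 4). The calibrated values only make sense with
  the inclusive comparison (two triangles sharing an edge *should* collide
  at threshold 2); a strict mode is available (`clique_overlap_strict`).
- **Growth frontier is static**, computed once from the seed clique; nodes
  added during growth do not contribute their own neighbors. This is the
  literal reading of the update N(Cᵢ) ← N(Cᵢ) − vᵢ, keeps growth bounded by
  the seed's neighborhood, and prevents runaway expansion under
  monotone-in-size scorers. A `dynamic_neighborhood` mode recomputes the
  frontier after each accepted node.
- **Merging is single-pass** over the score-ranked candidates: merged
  candidates keep scanning with their updated member set, removed ones never
  return, and already-scanned candidates are not revisited.
- **Tie-breaking everywhere** is (score desc, size desc, lexicographic
  member list asc). Determinism is part of the contract: identical inputs
  give byte-identical output catalogs.

Defaults: clique size ≥ 3, overlap threshold 2, `merg_thred` 0.8, 500
training iterations — the configuration that performs best in practice.

## Evaluation

NA matching uses ≥ ω (default 0.25); the five-fold protocol's dedup uses
strictly > 0.6 — both thresholds are implemented exactly as specified by
their definitions. PPV columns with zero totals (predictions disjoint from
every benchmark complex) contribute 0, the conservative convention. The
enrichment universe |V| defaults to the node count of the network being
analyzed. Hypergeometric p-values are computed in exact rational arithmetic
(integer binomials), so they are correct to the last floating-point digit at
any size used here; the test suite cross-checks them against
`scipy.stats.hypergeom`.

In the five-fold protocol, predictions are discarded when they match any
*training positive* at NA ≥ 0.9. Whether the intermediates should also
count as "training complexes" is ambiguous; they are excluded because by
construction they do not match true complexes, so removing their matches
would only delete potentially correct novel predictions. Fold assignment is
a seeded uniform shuffle (no stratification); per-fold negative samples are
drawn with seeds derived from the master seed.

## Synthetic benchmark

`BenchmarkSpec` defaults define the reference study condition: 500 proteins,
40 node-disjoint planted complexes with sizes 3–10 drawn from a power law
with exponent 2 (small complexes dominate, as in curated catalogs),
within-complex edge probability 0.9, background edge probability 0.005, a
depth-3 balanced GO tree with one signature leaf per complex, fully coherent
signature annotation, and a 20% uniform background annotation rate over 25
noise terms. Full coherence is the default because the benchmark's purpose
is unambiguous recovery measurement — edge noise is already injected through
p_in/p_out; lowering `annotation_coherence` emulates annotation
incompleteness, which additionally (and realistically) deletes within-complex
edges at the GO filter.

The generator emulates: sparsity, power-law complex sizes, dense complex
subgraphs, and GO-coherent co-complex annotation. It does **not** emulate:
overlapping complexes (disjoint by default so recovery metrics are
unambiguous), realistic degree distributions (background is Erdős–Rényi, not
scale-free), core–attachment complex architecture, evidence-code structure
in annotations, or inter-complex functional similarity. Passing the
recovery tests therefore demonstrates that the pipeline machinery works end
to end under its own assumptions, not that the reported real-data accuracy
transfers.

Training bundles split the planted complexes (default 50/50 train/held-out),
perturb each training positive by one node swap to fabricate the
intermediate category (a stand-in for another detector's near-misses), and
sample 120 random node sets as negatives — three per positive, the ratio
used at full scale (668/2004).

## Numerical and degenerate-input conventions

- Empty edge sets: mean edge weight 0; topological changes 0 when a cutoff
  level is empty; clustering coefficient 0 for nodes with ≤ 1 neighbor.
- Catalog readers drop complexes with < 2 distinct members; self-loops and
  duplicate edges are dropped/collapsed with logged counts.
- `overlap` and `na_score` reject empty sets rather than defining 0/0.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds are fixed offsets of the master seed, kept below 2³¹.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the reference condition (500 proteins, ~1000 interactions, 40 complexes) or
smaller; clique enumeration is cross-checked by exhaustive 2ⁿ search on
graphs of up to 12 nodes, and metric identities on catalogs over universes
of ≤ 40 proteins. These sizes make every check exact or statistically
unambiguous while keeping the whole suite under a few seconds.

## Known limitations

- Real-data headline numbers require DIP/MIPS/SGD-scale curated inputs and
  are out of scope here; the package reads the standard formats (TSV edge
  lists, OBO, GAF, one-complex-per-line catalogs) so those runs are possible
  when the data are available.
- The single-pass merge can leave overlapping candidates whose pairwise
  overlap straddles the threshold order-dependently; the fixed tie-break
  makes this deterministic but not order-free.
- Identifier harmonization between interaction and annotation namespaces is
  the caller's responsibility; IDs are opaque strings.
- The scorer is linear with no intercept and no regularization by design;
  heavily collinear features (e.g. the two densities) share weight mass
  arbitrarily, so individual fitted weights should be interpreted with care
  even though the ranking they induce is stable.
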