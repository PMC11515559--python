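# Methods

## Model and scope

`rasnet` treats a metabolic pathway as a metabolite-centric directed
graph: nodes are metabolites, each edge is a reaction annotated with a
gene–protein–reaction (GPR) rule and its pathway memberships. The model
deliberately avoids genome-scale constraint-based analysis (no flux
balance, no steady-state assumption, no objective function): activity is
inferred purely from transcript abundance plus local network topology.
That makes it applicable to any transcriptome dataset but also means the
scores are *transcriptional proxies* for reaction activity — they see
nothing of post-translational regulation, substrate availability or
actual flux.

### Reaction Activity Scores

For a reaction's GPR tree, AND nodes (subunits of one complex) evaluate
to the minimum of their children, OR nodes (isoenzymes) to the sum, and
leaves to the gene's normalized log expression; nested rules evaluate
recursively. Consequences worth knowing:

- RAS is monotone in expression and non-negative.
- Reactions with the *same* GPR get *identical* RAS rows — this is the
  shared-enzyme degeneracy the TP adjustments exist to break.
- A single-gene reaction's RAS is exactly that gene's expression.

**Missing genes** (in the graph, absent from the data) contribute 0 with
a warning by default; an AND node containing a missing gene therefore
evaluates to 0. A strict mode raises instead. The permissive default is
conservative and reproducible, but on sparsely annotated datasets it can
silence whole reactions — the warning lists the genes so this is
auditable.

### Normalization

Raw counts are normalized by the median-of-ratios method: each gene's
reference is its geometric mean across samples; a sample's size factor
is the median, over genes with strictly positive counts everywhere, of
count/reference (the median is taken on the ratio scale, not the log
scale — for an even number of reference genes these differ). Then
log10(x + 1). If no gene is positive in all samples the normalization
refuses and suggests a pseudo-reference; pre-normalized matrices can be
supplied directly (`normalize=False` in the workflow), matching the
common case of externally processed cohort data.

### Transition-probability adjustments

Per sample, W is the RAS-weighted adjacency and T its row normalization.
Degenerate rows (zero outgoing RAS) stay all-zero rather than uniform:
zero expression is read as zero activity, and inventing uniform flow
there would propagate mass through dead subgraphs.

- **Plain (W1 = W ∘ T).** Rows with positive out-RAS are probability
  vectors (checked to 1e-9 in tests); entries lie in [0, 1], so W1 never
  exceeds W.
- **Recursive (W2 = W ∘ Tᵃ).** Entries equal to 1 (tolerance 1e-12 —
  row-normalizing a sole outgoing edge is exact in IEEE arithmetic, the
  tolerance only guards accumulated error) are replaced by the largest
  plain TP among the source node's incoming edges; while that value is
  itself 1 the lookup recurses upstream. Lookups always use the
  *original* plain T, making the result order-independent and the
  operator idempotent. Ties among equally maximal incoming TPs resolve
  to the lexicographically smallest source id (only observable when the
  tie is at 1 and upstream branches differ). A node without incoming
  edges keeps 1; cycles are cut with a visited set, so a cycle of all-1
  TPs keeps 1.
- **Path (W3 = W ∘ Tᵇ).** All simple paths from a source metabolite x
  are enumerated depth-first along positive-TP edges; each path's
  probability is the product of plain TPs along it, and an edge's new
  value is the **sum** of the probabilities of all simple paths ending
  with that edge. On a DAG this equals the probability that a random
  walker from x traverses the edge, which is why sum (not max, also
  available via `combine="max"`) is the default; the equivalence is
  verified against an independent exhaustive enumerator in the tests.
  Edges unreachable from x get 0. Enumeration is capped (default 10⁶
  paths, hard error beyond) because simple-path counts can grow
  exponentially; on cyclic graphs entries can exceed 1 and are reported
  as-is with a warning. For GSL metabolism the natural x is
  lactosylceramide (C01290), the branch point of the lacto-/neolacto-,
  globo- and ganglio-series; W3 therefore depends on that choice, and
  there is no obvious analogue on a whole-genome network.

All three schemes reduce to the identity on a branchless chain (every TP
is 1), so adjustment only ever encodes *branching* information.

### Scaling for embedding

Before embedding, all-zero reaction rows (outside every possible path)
are removed and the remaining rows are z-scored across samples (sample
standard deviation, ddof = 1) to make path-length-dependent score scales
comparable; constant rows are dropped with a warning.

## Differential analysis

Per reaction: log2((mean_A + ε)/(mean_B + ε)) with ε = 1e-9 by default
(guards zero means; echoed in the output metadata), a two-sided
two-sample Kolmogorov–Smirnov test (`method="auto"`: exact for small
samples without ties, asymptotic otherwise), and Benjamini–Hochberg
adjustment over **all** reactions in the matrix. Both groups must have
at least 2 samples. The KS test is distribution-free but discrete at
small n, so null rejection rates sit slightly below nominal (~0.031
measured at 0.05 with n = 20 per group); this conservatism is inherent,
not a bug. Pathway activity is the plain sum of member-reaction values;
reactions in several pathways count toward each.

## Unsupervised exploration

UMAP (2-D, seeded via `random_state`, hence fully deterministic per
call) followed by HDBSCAN on the embedding coordinates with minimum
cluster size `min_pts`; HDBSCAN outliers form pseudo-cluster 0, real
clusters are numbered from 1. Defaults mirror small-cohort practice
(n_neighbors 3, min_dist 0.1, min_pts 5 for ~20-sample datasets;
n_neighbors 12–20, min_pts 10 for ~150-sample cohorts); all are
configurable, and `minpts_scan` reports cluster/outlier counts over a
minPts grid to guide the choice.

Stability: iteration i uses seed base_seed + i; per iteration the
per-sample coordinate sum x + y (the quantity plotted in stability line
plots), cluster labels, and three internal validity indices are
recorded. Indices are computed on the Euclidean geometry of the
*embedding* (that is what was clustered), with noise points excluded —
including the unclustered pseudo-cluster would score points that the
clustering explicitly declined to assign. With fewer than 2 non-noise
clusters the indices are NaN. The C-index is implemented from its
definition, (S_w − S_min)/(S_max − S_min) over pairwise distances;
Calinski–Harabasz and silhouette use scikit-learn. All three are checked
against independent brute-force implementations to 1e-9.

Markers: Welch t-tests per reaction, either cluster-vs-rest (default) or
`pairwise_max` (max p over tests against each other cluster — a marker
must separate the cluster from every other one individually); the two
coincide with exactly two clusters. Log-fold-change is the mean
difference on the already-log-scaled matrix. Zero-variance reactions get
p = 1 with a flag; clusters of size < 2 are skipped with a warning.

## Synthetic data

The generators emulate the two structural features the method needs:

- `toy_shared_enzyme_graph` / `parallel_chains`: a branch node feeding parallel
  chains whose corresponding steps share one gene, so unadjusted RAS is
  identical across chains and the branch reactions carry distinct genes.
- `simulate_counts`: negative-binomial counts (variance μ + φμ²) with
  per-gene baseline means log-uniform within a factor of 2 around
  `nb_mean` = 500 and dispersion φ = 0.1 — typical bulk RNA-seq scale
  and overdispersion — plus 50 unaffected background genes that
  stabilize the size factors. Group effects multiply a named gene's mean
  by 2^effect in one group only. Everything is determined by the seed.

What this does **not** emulate: realistic human GSL expression profiles,
gene–gene correlation structure, library-size artifacts, batch effects,
or cyclic/bidirectional metabolism. Passing tests therefore demonstrate
correctness of the computations and calibration under the stated
generative model, not biological validity on real cohorts.

## Problem sizes and numerical choices

The statistical checks use: 1000 replicates with 20 samples/group for
null calibration; 100 seeds with 30 samples/group and a 2-fold
single-enzyme effect for power; 100 seeds for planted-marker recovery
(+5 sd in a 15-sample cluster among 50); 100 embedding iterations on
100 well-separated samples for clustering stability; and 200 random DAGs
(4–12 nodes) for the path-probability oracle comparison (tolerance
1e-12). Edge and node orderings are fixed (sorted) so every matrix
layout is deterministic; per-iteration seeds are base_seed + i.

## Known limitations

- The path adjustment's source node is a modelling decision; results
  downstream of W3 change with it.
- Simple-path enumeration is exponential in the worst case; the cap
  turns pathological inputs into a hard error rather than a silent hang.
- KGML ingestion creates one edge per (substrate, product) pair of a
  reaction; reactions sharing an ordered node pair are merged with OR
  semantics (all ids kept in metadata) so the adjacency stays
  well-defined. Multi-substrate reactions are thus represented by
  parallel edges rather than hyperedges.
- The KS test ignores pairing and covariates; there is no gene-level
  differential expression here (use a dedicated DGE tool for that).
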