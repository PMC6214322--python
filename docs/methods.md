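# Methods

## Model

Genes are players in a coalitional game defined on the co-expression
network ⟨N, E⟩ and an a-priori weight vector k ∈ ℝ^N. A coalition S is
worth the summed weights of its closed neighborhood,
v(S) = Σ_{j ∈ S ∪ N_S(E)} k_j with v(∅) = 0: the more of the network's
a-priori mass a group of genes touches directly, the stronger the
group. The relevance index is the Shapley value of this game — the
average marginal contribution of each gene over all orderings of N —
which on this game class is the unique index satisfying efficiency
(Σρ = Σk), symmetry (equal-weight genes with identical neighbor sets
score equally), the dummy property (an isolated gene keeps its own
weight), and star-additivity (raising k_i by δ raises ρ_j by exactly
δ/(d_i+1) for every j in N_i ∪ {i} and changes nothing else). It
admits the closed form

    ρ_i = Σ_{j ∈ N_i(E) ∪ {i}} k_j / (d_j(E) + 1),

an O(|N|+|E|) computation: each gene j spreads its weight equally over
its closed star, and gene i collects the shares of its own closed star.
High ρ therefore flags genes adjacent to many low-degree genes — the
genes whose inhibition isolates leaves and fragments the network. The
index is linear in k; negative weights are permitted (harmless
generality, useful for testing linearity) although analyses use
nonnegative ones.

`shapley_bruteforce` evaluates the same value from the definition via
the subset-weighted sum Σ_{S ⊆ N\{i}} |S|!(n−|S|−1)!/n! · [v(S∪{i}) −
v(S)] with exact `fractions.Fraction` accumulation, guarded at n ≤ 12.
It exists solely as the independent oracle for the closed form; the
two are asserted to agree exactly (rational mode) on hundreds of random
graphs. The closed form also has an exact mode so the worked fixture
values (35/30, 56/30, 21/30) are reproduced bit-exactly rather than to
float tolerance.

## Network construction

Expression matrices are genes × samples with NaN/"NA" missing markers.
The preprocessing chain is: drop genes with strictly more than 80%
missing entries; impute the rest with the row mean; drop genes with
sample standard deviation strictly below 0.5; then connect genes whose
Pearson correlation strictly exceeds the threshold (default 0.8). All
three boundaries are strict because each rule is phrased as a strict
inequality ("greater than", "smaller than", "higher than"); ties at a
boundary are documented behavior, and the SD filter uses the n−1
denominator (configurable via `ddof`). Thresholding is on the raw
signed correlation by default; `use_absolute` exposes the |r|
convention used by some pipelines. All genes remain as nodes, so
isolated genes are first-class (the dummy axiom gives them ρ_i = k_i).

## Weight schemes

* **uniform** — k_i = 1: no prior knowledge; ρ becomes a pure
  connectivity index.
* **key-genes** — k_i = 1 on a given gene list, else 0: ρ_i then counts
  Σ 1/(d_j+1) over key-genes in i's closed star. Key ids missing from
  the network (typically filtered during preprocessing) warn by
  default and raise in strict mode.
* **cluster counts** — k_i = number of overlapping clusters containing
  i; genes in no cluster get 0, the only value consistent with
  "number of clusters it belongs to" when the clustering does not
  cover the network.

## Overlapping clustering

`greedy_cohesive_clusters` is a self-contained cohesiveness-based
overlapping clusterer in the style of greedy protein-complex detection:
cohesiveness f(S) = e_in/(e_in + e_bound + p·|S|), seeds taken in
decreasing-degree order (ties by label; seeds already covered are
skipped), growth/shrink by the single move that most increases f
(strict increase, so termination is guaranteed; ties prefer additions,
then the smallest label), merging of near-duplicates by the overlap
score |A∩B|²/(|A||B|) ≥ 0.8, and final filtering by minimum size 5 and
minimum internal edge density 0.5 (penalty p = 2). Edges are unweighted
since construction thresholds to a boolean adjacency. The defaults are
declared, not tuned; the pipeline equally accepts cluster files from
external tools, and reproducing any particular external clusterer's
output is a non-goal.

## Classical baselines and dialects

* Degree: raw neighbor count.
* Closeness: two dialects from BFS distances. `normalized` is the
  textbook (|N|−1)/Σ h(i,j); `reciprocal_sum` is 1/Σ h(i,j). They
  differ by the constant |N|−1 on connected graphs, but the worked
  comparison table this package reproduces prints reciprocal-sum values
  (0.048 = 1/21), so that is the default; the discrepancy between the
  two conventions is deliberate, documented behavior. On disconnected
  graphs sums are component-restricted and isolated nodes score 0, so
  downstream code tolerates degenerate closeness vectors.
* Betweenness: unnormalized, unordered pairs, endpoints excluded
  (Brandes via networkx, O(|N||E|)) — the convention that yields 48 and
  27 on the clique-flower fixture.
* Eigenvector: principal eigenvector of the adjacency matrix, scaled so
  the maximum entry is 1 (the normalization of the printed table).
  Power iteration runs on A + I rather than A: the shift preserves the
  principal eigenvector while making the dominant eigenvalue strictly
  largest in magnitude, so bipartite components (e.g. stars), on which
  plain adjacency iteration oscillates forever, converge. Defaults:
  tol 1e−10 in max-norm, max_iter 10000, all-ones start.

## Comparison machinery

Top-fraction selection takes m = ⌈fraction·|N|⌉ genes (the rule that
yields 108 from 2154 at 5%), breaking score ties by ascending label
(numeric-aware), so selections are deterministic and
input-order-invariant. Overlap tables count |list_p ∩ list_q| with a
companion Pearson correlation of the two measures' scores restricted to
the intersection (NaN below 2 common genes); correlations on
intersections are computed on scores, not ranks — the convention
adopted where the choice was open. Full-vector correlation tables mark
zero-variance vectors NaN. Neighbor coverage is |N_S(E) \ S|, the
exclusive convention (selected genes are not counted as their own
coverage). Removal profiles summarize connected components of the
induced subgraph after deletion as a size histogram with component and
singleton counts. Threshold robustness reruns
build → weights → ρ → top-fraction per cutoff and reports pairwise
selection overlaps; with an edgeless network all scores tie and the
selection degenerates to the lexicographically first genes, a
documented consequence of the tie rule.

## Synthetic data

Generators are pure functions of their arguments including the seed.

* `random_correlation_like_matrix(n, seed)`: symmetric, unit diagonal,
  off-diagonals i.i.d. Uniform[0,1] (upper triangle drawn, mirrored).
  This emulates a correlation structure for robustness studies in
  distribution only — real correlation matrices are positive
  semidefinite and have dependent entries, so overlap counts on this
  matrix characterize the workflow, not any particular dataset.
* `synthetic_expression`: planted co-expression modules as shared
  latent N(0,1) profile plus independent Gaussian noise with variance
  1/c − 1 so the expected within-module Pearson correlation is c;
  background genes independent; missing entries planted uniformly at a
  given rate. It emulates block co-expression structure but not
  microarray intensity scales, batch effects or heavy-tailed noise, so
  pipeline tests demonstrate correctness of the mechanics, not
  biological recovery rates on real arrays.
* Fixture topologies: the 21-node star of stars (5 branches × 3 leaves)
  and the 13-node clique flower (3 four-cliques on a hub). Leaf-to-
  branch assignment is fixed by consecutive labels; any assignment is
  isomorphic and every checked value is invariant to label permutation
  within roles.

## Problem sizes and numerical choices

The test suite checks oracle equivalence on 200 random graphs (n ≤ 9,
edge probabilities 0.2/0.5/0.8, rational weights in [0, 2]), the axiom
suite on 60 graphs, the robustness workflow at n = 1000 with cutoffs
0.7/0.8/0.9 (top-5% selection size 50), and linear-time scaling on a
sparse graph with 1e5 nodes and ~1e6 edges. Exact comparisons use
rational arithmetic end to end; float-mode agreement is asserted below
1e−9 (observed ~1e−15). Component ordering, selection tie-breaks, seed
ordering in clustering and writer line order are all deterministic, so
identical inputs give byte-identical outputs.

## Limitations

* Full-scale re-analysis of any real microarray compendium (download,
  normalization beyond the three filters, annotation) is out of scope;
  the pipeline accepts such data but ships no copy of it.
* Edge-weighted and directed graphs, soft thresholding, and
  significance-based edge selection are not supported.
* The clusterer is a deterministic stand-in for cohesiveness-based
  overlapping detection generally; its outputs will differ in detail
  from any specific external implementation.
* On clique-rich graphs the index rewards intra-clique cohesion rather
  than articulation (the clique-flower fixture illustrates this), so
  its fragmentation interpretation is strongest on sparse, tree-like
  networks.
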