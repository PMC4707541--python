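# Methods

This note documents the models and procedures implemented in `netora`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Network model and efficiency

The background network is an undirected graph over gene identifiers with
edge confidences in (0, 1]; unweighted input is stored with weight exactly 1.
Self-loops are dropped; duplicated pairs keep the maximum weight (and log a
warning). Gene identifiers are compared case-sensitively after whitespace
stripping; a `case_fold` configuration flag lowercases identifiers on input
for collections with inconsistent capitalization.

The background network efficiency bgNE is the mean of 1/SP_ij over all
ordered gene pairs, where SP_ij is the **hop-count** shortest path on the
binarized edge set and disconnected pairs contribute 0 (the Latora–Marchiori
convention, which keeps the statistic defined on fragmented networks). Hop
counts, not weight-derived distances, are used because bgNE is a density
measure bounded in [0, 1] — a bound that holds for hop counts (1/SP_ij ≤ 1)
but not for arbitrary weighted distances. With this convention bgNE equals 1
exactly on complete graphs and decreases with sparsity; the choice is
isolated inside `network_efficiency` should a distance-based variant ever be
wanted.

## Gene set-specific weighting

For a set S with k in-network members (members absent from the network are
dropped from k and from every sum, with the dropped count logged):

- e_i^S = d_i (k−1)/(m−1) for members and d_i k/(m−1) for non-members: the
  expected weighted degree into S when each of a gene's link units attaches
  to one of the other m−1 genes uniformly at random; a member cannot be its
  own neighbor, hence the k−1.
- w_i = (d_i^S − e_i^S)/e_i^S: dimensionless relative excess, zero at
  expectation. The degenerate case e_i^S = 0 (isolated gene) maps to w = 0,
  so isolated members still count as plain members (weight 1) rather than
  being discarded.
- W_i = 1 + 10·bgNE·w_i for w_i > 0, else 1 (members) / 0 (non-members).
  The linear amplification in bgNE compensates for the shrinking variance of
  w_i on dense networks: when nearly every gene touches every set, raw
  relative excesses are uniformly small and would otherwise carry little
  contrast. The factor guarantees W_i > 1 exactly when w_i > 0, for members
  and neighbors alike.
- W_ij = W_i·W_j·E_ij for existing links, 0 otherwise, and the diagonal
  convention W_ii = W_i² (equivalently E_ii = 1). The diagonal term is the
  single most consequential convention here: without it an interesting gene
  that belongs to S but is sparsely connected would contribute nothing to
  the score, erasing the plain-overlap signal that the method is meant to
  retain alongside the network signal. With it, bare membership contributes
  at least 1. It is switchable (`self_term: false`).
- G_i = Σ_{j∈S} W_ij: the contribution score, computed vectorized over the
  sparse adjacency (`W * (A[:, S] @ W[S])` plus the diagonal term). A
  triple-loop oracle implementation exists in the test suite and the two
  agree to 1e-10 on random inputs.

Two ablation variants are first-class configuration switches because they
are the natural controls for the weighting idea: `no_weight` replaces every
positive weight by an indicator (the network still selects *which* genes
count, but not *how much*), and `no_neighbor` zeroes all weights outside S
(membership-only scoring, but still network-reweighted inside the set).

## Test statistic and inference

The Enrichment Score of S is the mean G_i over the in-network interesting
genes (n′ of the n supplied genes; unmatched identifiers are reported, never
silently dropped). The null distribution draws n′ genes uniformly without
replacement from **all network genes** — the same universe the Fisher
baseline uses as its background — N = 1000 times by default (200 in the
desk-scale experiments below, where 5,000 set×list combinations are tested).

The empirical p-value is (r+1)/(N+1) with r the count of null draws at or
above the observed score; the add-one form never returns 0 and preserves
ordering. When r < 10 the empirical estimate is refined by a generalized
Pareto tail fit: the N_exc largest null values' excesses over a threshold
placed midway between the N_exc-th and (N_exc+1)-th largest are fit by
maximum likelihood (`scipy.stats.genpareto`, location fixed at 0), starting
from N_exc = 250 (capped at N/2 so the procedure is defined for small N) and
shrinking by 10 while an Anderson–Darling test rejects the fit at the 5%
level; the critical values are the Choulakian–Stephens asymptotic points for
a GPD with both parameters estimated, interpolated on the fitted shape. The
returned value is (N_exc/N)·(1 − F_GPD(ES − t)), floored at the smallest
positive float (a reported p of ~2.2e-308 therefore means "beyond the
support of the fitted tail", not a literal probability). If no tail size
yields an acceptable fit — common for lumpy, near-discrete nulls on small
unweighted networks — the method falls back to the add-one empirical
estimate with a warning.

Accuracy of the tail estimate is limited by information, not implementation:
extrapolating a two-parameter ML tail fit of 250 excesses down to the 1e-4
quantile carries a standard deviation of about 0.7 in log p (the
Cramér–Rao bound; the shape parameter dominates), so roughly two-thirds of
repeats land within a factor of 2 of truth and essentially all within an
order of magnitude — the estimator is median-unbiased but individual
estimates should be read at order-of-magnitude resolution. The unit tests
assert exactly that.

Bonferroni and Benjamini–Hochberg adjustments are computed across all tested
sets (`statsmodels`). Results are ranked by ascending final p, then
descending ES, then set name — a fully deterministic order required for
reproducible rank-based benchmarks. Per-set permutation seeds derive from
the master seed and a hash of the set name, so results are invariant to the
order of sets in the input collection.

The Fisher baseline restricts both the gene set and the interesting list to
the background (network genes) and computes the one-sided enrichment tail of
the 2×2 table via `scipy.stats.fisher_exact`, with the same adjustment and
ranking machinery.

## Cluster-and-filter

Gene-set relatedness is Jaccard similarity on the **full annotated member
sets**, not the network-filtered ones: redundancy is a property of the
annotation system and the partition is computed once, before any enrichment.
Edges are kept when similarity is strictly greater than 0.15 — low enough to
connect parent/child-style overlaps, high enough to keep the graph sparse.
Partitioning is iterated weighted-modularity maximization (networkx
`louvain_communities`, convergence threshold 1e-7, seeded); the partitioner
sits behind `partition_modules` so an alternative algorithm can be dropped
in. Nodes are inserted in sorted name order so the partition depends only on
the collection's content and the seed. Isolated gene sets become singleton
modules; module ids are renumbered contiguously from 1 by each module's
lexicographically smallest member. On small graphs the partition matches
exhaustive modularity maximization (verified in tests over all partitions of
up to 8 nodes).

Filtering keeps results below the significance level (raw final p by
default; an adjusted p by configuration), groups them by module, and
promotes the minimum-p member of each module as the marker (ties broken by
name), listing the remaining enriched members beneath it.

## Synthetic scenarios

The generator emulates the two regimes the weighting argument needs, and
nothing more:

- **Network**: a planted-partition graph — communities with intra-community
  edge probability `within_prob` against background `edge_prob`; equal
  probabilities degenerate to Erdős–Rényi. Weights are 1, or Uniform(0.5, 1]
  with the `weighted` flag.
- **Gene sets**: coherent sets are breadth-first network neighborhoods grown
  from a random seed gene (annotation terms that map onto dense network
  regions); incoherent sets are uniform draws. Names carry the ground truth
  (`coh###_c<community>` / `rand###`).
- **Interesting lists**: null mode draws uniformly from network genes.
  Planted mode draws ⌈effect·n⌉ genes from the target's *top-G pool* — the k
  network genes with the highest contribution score against the target.
  That pool deliberately mixes annotated members with strongly linked
  neighbors, modeling a hit list generated by the underlying functional
  module rather than by the annotation; the pool size k matches the set's
  own scale.

Default calibration condition: m = 500, edge probability 0.02 (about 10
partners per gene, the order of magnitude of a curated functional network's
high-confidence core), 50 sets of 10–50 genes, half coherent, lists of 30.
Planted-recovery condition (`planted_scenario`): m = 300, ten communities
with `within_prob` 0.3, 20 sets of 10–25 genes with exactly one coherent set
per community — one set per community because two coherent sets sharing a
community would both legitimately represent the planted signal, making the
"rank of the target" ill-defined — effect 0.6, lists of 30.

The calibration experiment (`null_calibration`) repeats: draw a null list,
run the full pipeline, record which sets fall below α; it reports per-set
frequencies of random significance and their median, which for an unbiased
method is ≈ α. At the default desk scale the observed median is 4–5% at
α = 0.05.

**What these fixtures do not capture**: scale-free degree distributions and
hubs of real interactomes, heavy annotation nesting (GO-style DAGs), edge
confidence structure correlated with degree, and list sizes in the hundreds.
Passing the synthetic benchmarks shows the machinery is calibrated and can
recover a network-concentrated signal at small scale; it does not by itself
establish performance on a specific curated network.

A known consequence of the planted design: because the top-G pool contains
annotated members, the membership overlap alone is already decisive at this
scale, so the Fisher baseline also ranks the planted target first in nearly
every draw — the planted benchmark separates the weighted method from its
own ablations, not from Fisher. Separating from Fisher would require signal
placed exclusively in unannotated neighbors.

## Numerical and degenerate-input choices

- bgNE on fragmented networks: disconnected pairs contribute 0; networks
  with fewer than 2 genes are rejected.
- Permutation counts below 100 are rejected (the add-one estimator and the
  tail trigger are meaningless below that); tail fitting requires at least
  30 null samples.
- Edge rewiring keeps one endpoint, redraws the other uniformly until the
  result is neither a self-loop nor a duplicate; edge count, gene roster and
  the weight multiset are preserved exactly.
- Edge removal deletes ⌊fraction·|E|⌋ edges chosen uniformly without
  replacement; genes are never removed.
- All random draws go through `numpy.random.default_rng` seeded from
  explicit integers; identical seeds give byte-identical output tables.

## Problem sizes

The shipped experiments run at desk scale by choice: calibration uses 100
null lists × 50 sets × 200 permutations (~half a minute on one CPU), and the
planted benchmark uses 50 seeds × 3 weighting variants. All sizes are
parameters of the public API and scale up directly.

## Known limitations

- The GPD refinement resolves p-values far below 1/N only at
  order-of-magnitude resolution (see above), and degrades to the empirical
  estimate on strongly discrete nulls.
- The enrichment score is a raw mean of contribution scores, so scores are
  not comparable *across* gene sets of different size and density; only the
  per-set permutation p-values are.
- Modularity-based partitioning inherits the resolution limit of modularity;
  very small redundancy families connected by weak edges can merge.
- Directed networks, multigraphs and weighted-distance shortest paths are
  out of scope.
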