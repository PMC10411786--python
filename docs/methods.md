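# Methods

This note records the model choices, defaults, numerical conventions and
known limitations behind the package, in the order the pipeline runs.

## Preprocessing

Mixed clinical tables are made numeric by **frequency encoding**: each
categorical value is replaced by its relative frequency (count/N) in its
own column, computed per column (never jointly), which keeps encoded
features on [0, 1] before standardization. All columns are then
**z-scored** with the sample (n−1) standard deviation; constant columns map
to all zeros rather than dividing by zero. The metric on the resulting
matrix is Euclidean distance — the conventional choice once features share
a z-score scale. Missing values are rejected (optionally after a
drop-rows pass); imputation is deliberately out of scope because any
imputation model would leak assumptions into the topology.

## Lens, cover and partial clustering

Supported lenses are the identity, single-coordinate projection, and 1- or
2-D principal-component projection (default `pca2`). The lens is the one
genuinely dataset-dependent choice: a 2-D lens on data whose structure is
one-dimensional slices clusters along a pure-noise axis, producing chains
of Mapper nodes that community detection will legitimately cut (see
Limitations). For data separating along a single dominant direction,
`pca1` is the faithful choice. PCA component signs are fixed (largest
absolute loading made positive) so runs are reproducible across BLAS
builds.

The cover is uniform: per lens dimension with observed range `[lo, hi]`,
interval length `ℓ = (hi−lo)/(r − (r−1)g)`, stride `ℓ(1−g)`, giving `r`
intervals whose consecutive overlap is exactly `g·ℓ` and whose union ends
exactly at `hi`. Membership is by closed-interval containment, so a point
on a shared boundary belongs to every covering cube. Empty cubes are
dropped. Degenerate ranges (constant lens coordinate) produce
point-containing intervals.

Defaults `r = 5`, `g = 0.3`. The resolution default targets the cohort
scale the package is written for (a few hundred observations): with a 2-D
lens, `r = 5` keeps the expected cube occupancy above ~10 observations, so
single observations rarely strand in non-overlapping cubes. An early
default of `r = 6` was revised after the canonical three-blob fixture
showed exactly that failure mode: a blob outlier alone in a cube shared
with nothing, whose cluster membership is then undetermined by the graph.
No default suits every dataset; the stability grid (below) is the
method's own device for choosing `(r, g)`, and both remain configuration.

Within each bin, observations are clustered on their **original**
coordinates with single-linkage agglomerative clustering. The dendrogram
is cut inside the first *gap* of the merge-height sequence exceeding
mean + 1 SD of all merge heights in the bin: unimodal bins (heights dense,
no outsized jump) stay whole, while bins straddling separated groups split
at the jump. Bins with ≤ 2 members, or with all-identical points, form one
cluster. The clusterer is pluggable; this default is parameter-light and
standard for Mapper-style partial clustering.

## Mapper graph conventions

One node per within-bin cluster. Edge weight between distinct nodes is the
shared-observation count; every node carries a self-loop weighted by its
cardinality, which is the shared-observation rule applied to a node and
itself and makes self-loops commensurate with the other weights. The walk
model honors self-loops (a walker may stay put), and node connectivity
counts the self-loop once.

## Walk-likelihood partitioning

The transition matrix is `T(u,v) = w(u,v)/k_u` with `k_u` the weighted
degree. Expected visits `V(n,c)` — the mean over start nodes `n'` in
community `c` of `Σ_{l=1..l_max} [T^l](n',n)` — are accumulated by
iterated sparse matrix–vector products; `T^l` is never materialized.
`l_max` defaults to `⌈log n⌉ + 2`, a logarithmic mixing horizon.

**Reassignment rule.** Node `n` moves to `argmax_c P(n|c)` where
`P(n|c) = V(n,c)/Σ_{n''} V(n'',c)` is the normalized visit frequency, ties
broken toward the lowest community index. This is a posterior with a
*uniform* prior over communities. A connectivity-mass prior
(`P(c) ∝ K_c`) was evaluated and rejected: `V(n,c)` is already a per-walk
average, so community size does not inflate it, and the mass prior makes
the largest community absorb every node whose visit evidence is balanced —
in pilot runs it collapsed clearly separated planted partitions to a
single community on half the seeds. The rule lives in one function
(`walks._posterior`) so alternative likelihood models can be swapped in.
Convergence is assignment fixed-point or 100 sweeps (flagged).

**Modularity** is the weighted Newman form
`Q = Σ_c [W_in(c)/2W − (K_c/2W)²]` with the adjacency total `2W` counting
self-loops once on the diagonal. Under this convention two disjoint unit
triangles partitioned as themselves score exactly 0.5, and any single
community scores 0.

**WLCF** starts from one community and iterates: (i) bifurcate every
community by a seeded random balanced split refined with WLA on the
community's induced subgraph (isolated-in-subgraph nodes are tolerated
there — their walkers vanish and they keep their side of the split);
(ii) refine globally with WLA; (iii) merge greedily, always the pair with
the largest positive ΔQ, where
`ΔQ(a,b) = 2[E_ab/2W − K_aK_b/(2W)²]`. The outer loop stops when the
community count repeats (hard cap 20, flagged).

## Network of instances and the final clustering

The instance network is assembled from two sparse membership indicators:
`W = B_V B_Vᵀ + B_C diag(1/|bin|) B_Cᵀ`, where `B_V` marks node
membership and `B_C` bin membership. Off-diagonal entries count shared
Mapper nodes plus bin co-occurrence at weight `1/|bin|`; the two rules are
combined additively (both are co-occurrence evidence between the same
pair; the combiner is one expression and easily swapped). Diagonal
entries give every observation a self-edge of `#nodes + Σ 1/|bin|`, so no
node is ever isolated (every observation sits in ≥ 1 node and ≥ 1 bin).
The bin term is normalized by bin cardinality so that co-occurring in a
small, specific bin counts for more than co-occurring in a catch-all bin.

The final WLA starts from a disjoint initialization derived from the
overlapping communities: each observation goes to the community whose
Mapper nodes contain it most often, ties to the lowest index. The result
has at most `c` communities (the WLCF-detected count) and assigns every
observation exactly once.

## Agreement scoring and the stability grid

Mutual information uses natural logarithms with `0·log(0/x) = 0`;
`NMI = 2I(U,U')/(I(U,U)+I(U',U'))`, which equals mutual information
normalized by the arithmetic mean of the two entropies (the cross-check in
the test suite uses scikit-learn's implementation under exactly that
normalization). NMI is undefined, and raises, only when both clusterings
are a single cluster.

The stability grid runs the full pipeline at every `(r, g)` cell with one
shared seed — so differences between cells reflect parameters only — and
scores each cell by the mean NMI against its adjacent cells: 8 in the
interior, 5 on edges, 3 at corners (boundary cells average over existing
neighbors; a failed cell is skipped by its neighbors and carries no
score). When two adjacent cells both return the trivial single-cluster
solution they are identical and score 1. The pass threshold is a required
user input with no default: what counts as stable enough depends on the
dataset.

## Synthetic fixtures

All generators are pure functions of `(params, seed)` through
`numpy.random.default_rng` — bit-reproducible, no global state.

- `gaussian_blobs`: isotropic clouds around given centers. The canonical
  test fixture is 3 blobs of 100 points at 20σ separation, where nearest-
  center classification is essentially error-free, so planted labels are a
  valid ground truth.
- `noisy_circle`: radial-noise circle, exercising the loop topology a
  Mapper graph should express as a cycle.
- `planted_partition_graph`: unit-weight stochastic block model with
  within-probability `p_in` and between-probability `p_out`; nodes left
  isolated by the draw are rewired to one random within-block neighbor so
  the walk-partitioning connectivity contract holds.
- `mixed_cohort`: the clinical-table stand-in. Numeric features are
  unit-variance Gaussians whose group means are spaced `effect·σ` apart,
  with the group order permuted per feature so no single feature carries
  all the separation. Categorical features are three-level multinomials
  with a moderate fixed lean toward a group-preferred level — deliberately
  not scaled by `effect`, because a near-deterministic category splits
  each group into satellite Mapper components and turns one planted
  subgroup into several real clusters. The binary outcome steps its
  success probability by `outcome_gap` between consecutive groups around
  a base rate of 0.5.

What the fixtures do *not* emulate: correlated features, heavy-tailed or
skewed clinical measurements, informative missingness, and class
imbalance beyond what random group assignment produces. Passing tests
demonstrate that the machinery is implemented correctly and recovers
planted structure under clean separation; they do not certify performance
on real cohort data, where lens choice and `(r, g)` selection dominate.

## Problem sizes

The test and example runs use a few hundred observations (300-point
clouds, 240-patient cohorts, 200-node graphs) and 5×5 parameter grids —
sizes at which every oracle (triple-loop network reference, brute-force
modularity, walk enumeration) is exact and fast, and representative of
the cohort scale the method targets.

## Known limitations

- **Lens sensitivity.** A lens with uninformative dimensions slices
  structure along noise; the resulting node chains are legitimately cut by
  modularity-based community detection (observed and documented on a
  two-blob fixture under a 2-D lens; resolved by the 1-D lens).
- **Cover-boundary stranding.** At high resolution, outliers can occupy a
  cube that overlaps nothing; such an observation is topologically
  disconnected and its final label is decided by the initialization, not
  by evidence. Lower resolution or higher gain removes the artifact; the
  stability grid flags the affected configurations through depressed
  neighbor agreement.
- **Modularity resolution effects.** Long chains of small nodes can be
  split even when they represent one structure — inherited from
  modularity itself.
- **Walk-likelihood realization.** The reassignment rule is a documented
  realization of "Bayesian update from expected visit counts"; other
  likelihood models (e.g. Poisson visit models) may behave differently
  and can be swapped in at the single function noted above.
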