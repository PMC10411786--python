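# mapperplus

Agnostic disjoint clustering of high-dimensional tabular data, built for
patient stratification: finding subgroups in a cohort when the number of
subgroups is unknown, every observation must be assigned (excluding the
ambiguous ones would bias any downstream comparison), and the result has to
be stable under small parameter changes before anyone acts on it.

## The method

The pipeline combines a topological summary with random-walk community
detection, in eight steps:

1. **Lens.** Project the preprocessed data matrix `X ⊂ R^d` through a lens
   `f : X → Y ⊂ R^m` (identity, a coordinate, or 1-/2-D principal
   components).
2. **Cover.** Tile the lensed range with `r^m` overlapping hypercubes —
   `r` intervals per dimension, adjacent intervals overlapping by the gain
   fraction `g`.
3. **Partial clustering.** Cluster each hypercube's preimage `f⁻¹(C_n)` on
   the *original* coordinates (single-linkage with a merge-height gap cut).
4. **Mapper graph** `G_M(V_M, E_M)`: one node per within-bin cluster; an
   edge of weight `|members_u ∩ members_v|` between nodes sharing
   observations; a self-loop of weight `|members_u|` on every node.
5. **Community count.** The walk-likelihood community finder (WLCF)
   partitions `G_M` and determines the number of communities `c` by
   bifurcation, walk-likelihood refinement, and modularity-increasing
   merging — no user-supplied cluster count.
6. **Overlapping clusters.** The union of member observations over each
   node community; overlapping because Mapper nodes share observations.
7. **Network of instances** `G`: one node per observation, with
   `w(i,j) = #{nodes containing i and j} + Σ_{bins ∋ i,j} 1/|bin|`
   (self-edges included), translating the overlapping topology into a
   per-observation graph.
8. **Disjoint clustering.** The walk-likelihood algorithm (WLA) on `G`
   with `c` communities: iterative Bayesian reassignment by expected
   random-walk visit counts, seeded from the overlapping clusters. Every
   observation receives exactly one label.

Two clusterings `U` (N×m) and `U'` (N×m') are compared by normalized
mutual information,

    NMI(U, U') = 2 I(U, U') / (I(U, U) + I(U', U')),

with `I` the mutual information of the membership probabilities
`P_U(c) = N⁻¹ Σ_i U_ic` and `P_UU'(c,c') = N⁻¹ Σ_i U_ic U'_ic'`.
NMI is 1 iff the clusterings are identical and 0 when they are mutually
random. A **stability grid** runs the pipeline at every cell of an
`(r, g)` grid and scores each cell by the mean NMI against its (up to 8)
adjacent cells; cells on a high plateau are parameter choices whose
clustering is insensitive to perturbation, which is the selection criterion
when no ground truth exists.

## Worked example

`examples/cluster_blobs.py` clusters 300 points in three Gaussian blobs
placed 20 standard deviations apart:

```text
observations assigned : 300 of 300
clusters detected     : 3 (sizes [100, 100, 100])
NMI vs planted groups : 1.000
```

All 300 observations are assigned (no exclusions), the community finder
detects 3 clusters without being told, and the disjoint labels reproduce
the planted blobs exactly. `examples/cohort_stratification.py` runs the
same pipeline on a synthetic mixed categorical/continuous cohort with
subgroup-linked binary outcomes:

```text
patients clustered : 240 of 240 (none excluded)
clusters detected  : 3 (planted subgroups: 3)
NMI vs planted     : 1.000

cluster  n    outcome rate
   0     93     0.76
   1     76     0.55
   2     71     0.39
```

The recovered clusters separate the planted outcome rates — the pattern a
stratification of real patients aims for. `examples/stability_selection.py`
prints the 5×5 stability grid (interior plateau ≥ 0.9 on this fixture) and
`examples/community_detection.py` demonstrates WLCF alone on a planted
4-block graph.

A thin CLI mirrors the two workflows:

```bash
mapperplus cluster --input data.csv --resolution 5 --gain 0.3 --seed 0 --out labels.csv
mapperplus stability --input data.csv --threshold 0.9 --out grid.csv
mapperplus fixtures --out-dir fixtures  # regenerate synthetic inputs
```

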