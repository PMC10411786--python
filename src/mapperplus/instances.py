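"""From the overlapping Mapper graph to a disjoint clustering of every
observation: the network of instances and the 8-step pipeline.

A Mapper graph cannot be read as a clustering directly: its nodes overlap,
so cutting the graph assigns some observations to several clusters while
excluding none is essential (in patient stratification, dropping the
ambiguous patients biases every downstream comparison).  The resolution here
is a *network of instances* G: one node per observation, with edge weights

    w(i, j) = #{Mapper nodes containing both i and j}
              + Σ_{bins B containing both i and j} 1 / |B|        (i ≠ j)
    w(i, i) = #{Mapper nodes containing i}
              + Σ_{bins B containing i} 1 / |B|,

i.e. co-membership in within-bin clusters plus bin co-occurrence normalized
by bin size, combined additively.  Community detection on the Mapper graph
fixes the number of clusters c; walk-likelihood reassignment on G, seeded
from the overlapping communities, then yields a disjoint c-way clustering of
all N observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp

from .mapper import MapperGraph, PullbackBin, mapper_graph_from_data
from .preprocess import DataMatrix
from .walks import AssignmentMatrix, WeightedGraph, wla, wlcf

__all__ = [
    "OverlappingClusters",
    "overlapping_clusters",
    "build_instance_network",
    "disjoint_cluster",
    "run_pipeline",
    "PipelineResult",
]


@dataclass(frozen=True)
class OverlappingClusters:
    """Communities of observations obtained by taking the union of the
    member observations over all Mapper nodes in each graph community.
    Overlap is expected: a shared observation sits in several sets."""

    communities: tuple[frozenset, ...]

    @property
    def m(self) -> int:
        return len(self.communities)

    def covered(self) -> set[int]:
        out: set[int] = set()
        for c in self.communities:
            out |= c
        return out


def overlapping_clusters(
    mapper_graph: MapperGraph, node_partition: AssignmentMatrix
) -> OverlappingClusters:
    """Lift a disjoint partition of Mapper NODES to (possibly overlapping)
    communities of observations."""
    if node_partition.n_obs != mapper_graph.n_nodes:
        raise ValueError("partition size does not match the Mapper graph")
    labels = node_partition.labels()
    sets: list[set[int]] = [set() for _ in range(node_partition.m)]
    for node in mapper_graph.nodes:
        sets[labels[node.node_id]].update(node.members)
    return OverlappingClusters(communities=tuple(frozenset(s) for s in sets))


def build_instance_network(
    mapper_graph: MapperGraph, bins: list[PullbackBin], n_obs: int | None = None
) -> WeightedGraph:
    """Build the network of instances from a Mapper graph and its bins.

    Implemented with sparse membership matrices: with B_V the N x |V_M|
    node-membership indicator and B_C the N x |bins| bin indicator,

        W = B_V B_V^T + B_C diag(1/|bin|) B_C^T

    whose off-diagonal entries are exactly the additive node + bin rule and
    whose diagonal gives the self-edge weights.
    """
    covered = mapper_graph.covered_observations()
    if n_obs is None:
        n_obs = max(covered) + 1
    binned = set()
    for b in bins:
        binned.update(b.members)
    if not binned <= covered | set(range(n_obs)):
        raise ValueError("bins refer to out-of-range observations")
    stranded = binned - covered
    if stranded:
        raise ValueError(
            f"observations {sorted(stranded)[:5]} appear in bins but in no "
            "Mapper node: partial clustering dropped data"
        )
    rows, cols = [], []
    for j, node in enumerate(mapper_graph.nodes):
        rows.extend(node.members)
        cols.extend([j] * len(node.members))
    b_node = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_obs, mapper_graph.n_nodes)
    )
    rows, cols, vals = [], [], []
    for j, b in enumerate(bins):
        k = len(b)
        rows.extend(b.members)
        cols.extend([j] * k)
        vals.extend([1.0 / k] * k)
    b_bin = sp.csr_matrix((vals, (rows, cols)), shape=(n_obs, len(bins)))
    b_bin_raw = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_obs, len(bins))
    )
    w = b_node @ b_node.T + b_bin_raw @ b_bin.T
    w = (w + w.T) / 2.0  # exact symmetry against summation order
    return WeightedGraph(adjacency=w.tocsr())


def initial_assignment(
    overlapping: OverlappingClusters,
    mapper_graph: MapperGraph,
    node_partition: AssignmentMatrix,
    n_obs: int,
) -> AssignmentMatrix:
    """Disjoint starting point for the final reassignment step.

    Each observation goes to the community in whose union it appears; an
    observation in several goes to the one whose Mapper nodes contain it
    most often, ties to the lowest community index.
    """
    node_labels = node_partition.labels()
    # count, per observation, how many Mapper nodes of each community hold it
    counts = np.zeros((n_obs, overlapping.m), dtype=int)
    for node in mapper_graph.nodes:
        c = node_labels[node.node_id]
        for i in node.members:
            counts[i, c] += 1
    uncovered = np.flatnonzero(counts.sum(axis=1) == 0)
    if uncovered.size:
        raise ValueError(f"observations {uncovered[:5].tolist()} not covered")
    labels = np.argmax(counts, axis=1)  # ties -> lowest index
    return AssignmentMatrix.from_labels(labels)


def disjoint_cluster(
    network: WeightedGraph,
    overlapping: OverlappingClusters,
    mapper_graph: MapperGraph,
    node_partition: AssignmentMatrix,
    l_max: int | None = None,
    seed: int | None = None,
) -> tuple[AssignmentMatrix, bool]:
    """Final step: WLA on the instance network with c communities.

    The initial disjoint assignment is derived from the overlapping
    communities; the result has at most c clusters and covers all N
    observations.  Returns (assignment, converged).
    """
    if not overlapping.covered() <= set(range(network.n_nodes)):
        raise ValueError("network node set does not cover the communities")
    u0 = initial_assignment(overlapping, mapper_graph, node_partition, network.n_nodes)
    return wla(network, u0, l_max=l_max)


@dataclass
class PipelineResult:
    """Everything a full pipeline run produces."""

    assignment: AssignmentMatrix
    mapper_graph: MapperGraph
    instance_network: WeightedGraph
    overlapping: OverlappingClusters
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def labels(self) -> np.ndarray:
        return self.assignment.labels()


def run_pipeline(
    data: DataMatrix,
    lens: str = "pca2",
    resolution: int = 5,
    gain: float = 0.3,
    clusterer: str = "single_linkage_gap",
    l_max: int | None = None,
    seed: int | None = 0,
) -> PipelineResult:
    """Run the full 8-step pipeline on a preprocessed matrix.

    1-2. lens + cover, 3. per-bin partial clustering, 4. Mapper graph,
    5. community detection on the Mapper graph (fixes the cluster count c),
    6. overlapping observation communities, 7. network of instances,
    8. walk-likelihood disjoint clustering with c communities.

    Deterministic given (data, config, seed); diagnostics record per-stage
    sizes and convergence flags.
    """
    n = data.n_obs
    diagnostics: dict[str, Any] = {"n_obs": n, "resolution": resolution, "gain": gain,
                                   "lens": lens, "seed": seed}
    if n == 1:
        # degenerate input: a single observation is its own cluster
        from .mapper import MapperNode

        assignment = AssignmentMatrix.from_labels([0])
        mg = MapperGraph(
            nodes=(MapperNode(node_id=0, members=(0,), cube_index=(0,)),),
            edges={(0, 0): 1.0},
        )
        net = WeightedGraph(adjacency=sp.csr_matrix(np.array([[2.0]])))
        diagnostics.update(n_bins=1, n_nodes=1, n_edges=0, m_detected=1,
                           wlcf_converged=True, wla_converged=True)
        return PipelineResult(
            assignment=assignment,
            mapper_graph=mg,
            instance_network=net,
            overlapping=OverlappingClusters(communities=(frozenset({0}),)),
            diagnostics=diagnostics,
        )
    try:
        mapper_graph, bins = mapper_graph_from_data(
            data, lens=lens, r=resolution, g=gain, clusterer=clusterer, seed=seed
        )
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise RuntimeError(f"mapper stage failed: {exc}") from exc
    diagnostics["n_bins"] = len(bins)
    diagnostics["n_nodes"] = mapper_graph.n_nodes
    diagnostics["n_edges"] = sum(1 for (a, b) in mapper_graph.edges if a != b)

    node_graph = WeightedGraph.from_mapper_graph(mapper_graph)
    node_partition, wlcf_ok = wlcf(node_graph, l_max=l_max, seed=seed)
    diagnostics["m_detected"] = node_partition.m
    diagnostics["wlcf_converged"] = wlcf_ok

    overlapping = overlapping_clusters(mapper_graph, node_partition)
    network = build_instance_network(mapper_graph, bins, n_obs=n)
    assignment, wla_ok = disjoint_cluster(
        network, overlapping, mapper_graph, node_partition, l_max=l_max, seed=seed
    )
    diagnostics["wla_converged"] = wla_ok
    diagnostics["m_final"] = assignment.m
    if assignment.n_obs != n:
        raise AssertionError("pipeline lost observations")  # pragma: no cover
    return PipelineResult(
        assignment=assignment,
        mapper_graph=mapper_graph,
        instance_network=network,
        overlapping=overlapping,
        diagnostics=diagnostics,
    )
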