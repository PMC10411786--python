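"""Mapper graph construction: lens, cover, pullback, partial clustering.

Mapper summarizes a point cloud (X, d_Euclid) as a graph.  A lens
f : X -> Y ⊂ R^m projects the data to low dimension; an overlapping cover of
r^m hypercubes tiles the lensed range; each hypercube's preimage is
clustered on the *original* coordinates; every within-bin cluster becomes a
graph node and nodes that share observations are joined by an edge weighted
by the shared count.  Because adjacent hypercubes overlap by a gain fraction
g, an observation can sit in several bins and hence in several nodes — the
overlap is what lets the graph record connectivity between regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .preprocess import DataMatrix

__all__ = [
    "LensImage",
    "CoverSpec",
    "PullbackBin",
    "MapperGraph",
    "apply_lens",
    "build_cover",
    "pullback",
    "partial_cluster",
    "build_mapper_graph",
]


@dataclass(frozen=True)
class LensImage:
    """Lensed coordinates Y ⊂ R^m, row-aligned with the source matrix."""

    coords: np.ndarray
    lens_name: str

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if not np.isfinite(c).all():
            raise ValueError("lens image contains non-finite coordinates")
        object.__setattr__(self, "coords", c)

    @property
    def n_obs(self) -> int:
        return self.coords.shape[0]

    @property
    def m(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class CoverSpec:
    """Uniform cover of the lensed range by r^m overlapping hypercubes.

    ``intervals[dim]`` is an (r, 2) array of [lower, upper] bounds; the
    Cartesian product over dimensions enumerates the hypercubes.
    """

    r: int
    g: float
    intervals: tuple[np.ndarray, ...]

    @property
    def m(self) -> int:
        return len(self.intervals)

    @property
    def n_cubes(self) -> int:
        return self.r ** self.m


@dataclass(frozen=True)
class PullbackBin:
    """Observation indices whose lens values fall inside one hypercube."""

    cube_index: tuple[int, ...]
    members: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MapperNode:
    """One within-bin cluster: node id, member observations, source cube."""

    node_id: int
    members: tuple[int, ...]
    cube_index: tuple[int, ...]


@dataclass(frozen=True)
class MapperGraph:
    """Weighted Mapper graph G_M(V_M, E_M) with self-loops.

    ``edges`` maps unordered node-id pairs (a <= b) to weights: for a != b
    the number of shared observations, for a == b the node cardinality
    (a node shares all its members with itself).
    """

    nodes: tuple[MapperNode, ...]
    edges: dict[tuple[int, int], float]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def covered_observations(self) -> set[int]:
        out: set[int] = set()
        for node in self.nodes:
            out.update(node.members)
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.node_id, members=node.members, cube=node.cube_index)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            for (a, b), w in sorted(self.edges.items()):
                fh.write(f"{a}\t{b}\t{w:g}\n")

    def write_memberships(self, path, row_ids=None) -> None:
        import pandas as pd

        rows = []
        for node in self.nodes:
            for i in node.members:
                rid = row_ids[i] if row_ids is not None else i
                rows.append((node.node_id, rid))
        pd.DataFrame(rows, columns=["node_id", "row_id"]).to_csv(path, index=False)


def apply_lens(data: DataMatrix, lens: str = "pca2", seed: int | None = None) -> LensImage:
    """Project the data through a lens.

    Supported lenses: ``identity``, ``col:<j>`` (coordinate projection),
    ``pca1`` / ``pca2`` (principal-component projection).  The default,
    2-D principal components, is a sensible generic choice; the lens is a
    configuration option because no single lens suits every dataset.
    """
    x = data.values
    if lens == "identity":
        return LensImage(coords=x.copy(), lens_name=lens)
    if lens.startswith("col:"):
        j = int(lens.split(":", 1)[1])
        if not 0 <= j < data.n_features:
            raise ValueError(f"column index {j} out of range")
        return LensImage(coords=x[:, j].copy(), lens_name=lens)
    if lens in ("pca1", "pca2"):
        from sklearn.decomposition import PCA

        m = 1 if lens == "pca1" else 2
        if m >= data.n_features:
            if m == data.n_features:
                # projection onto all components is a rotation; allow it
                pass
            else:
                raise ValueError(
                    f"lens dimension {m} exceeds data dimension {data.n_features}"
                )
        m_eff = min(m, data.n_features, data.n_obs)
        pca = PCA(n_components=m_eff, svd_solver="full", random_state=seed)
        coords = pca.fit_transform(x)
        if coords.shape[1] < m:
            coords = np.pad(coords, ((0, 0), (0, m - coords.shape[1])))
        # fix component sign for determinism across BLAS builds
        for k in range(coords.shape[1]):
            col = coords[:, k]
            j = int(np.argmax(np.abs(col)))
            if col[j] < 0:
                coords[:, k] = -col
        return LensImage(coords=coords, lens_name=lens)
    raise ValueError(f"unsupported lens {lens!r}")


def build_cover(lens_image: LensImage, r: int, g: float) -> CoverSpec:
    """Build the uniform cover: r intervals per dimension with overlap g.

    Per dimension with observed range [lo, hi]: interval length
    l = (hi - lo) / (r - (r-1) g), stride s = l (1 - g), interval i =
    [lo + i s, lo + i s + l].  Consecutive intervals then overlap by exactly
    g*l and the last interval's upper bound lands on hi.  A degenerate
    dimension (hi == lo) gets point-containing intervals.
    """
    if r < 1:
        raise ValueError("resolution r must be >= 1")
    if not 0.0 < g < 1.0:
        raise ValueError("gain g must lie strictly between 0 and 1")
    intervals = []
    for dim in range(lens_image.m):
        col = lens_image.coords[:, dim]
        lo, hi = float(col.min()), float(col.max())
        span = hi - lo
        if span == 0.0 or r == 1:
            bounds = np.repeat([[lo, hi]], r, axis=0).astype(float)
        else:
            length = span / (r - (r - 1) * g)
            stride = length * (1.0 - g)
            starts = lo + stride * np.arange(r)
            bounds = np.column_stack([starts, starts + length])
            bounds[-1, 1] = hi  # guard against rounding past the data range
        intervals.append(bounds)
    return CoverSpec(r=r, g=g, intervals=tuple(intervals))


def pullback(lens_image: LensImage, cover: CoverSpec) -> list[PullbackBin]:
    """Assign observations to hypercubes by closed-interval containment.

    A point on a shared boundary belongs to every covering cube.  Empty
    cubes are dropped; the union of bins covers all observations.
    """
    if cover.m != lens_image.m:
        raise ValueError("cover dimension does not match lens image")
    # per-dimension membership masks: in_dim[d][i] = N-bool vector
    masks = []
    for dim in range(cover.m):
        col = lens_image.coords[:, dim]
        b = cover.intervals[dim]
        masks.append([(col >= b[i, 0]) & (col <= b[i, 1]) for i in range(cover.r)])
    bins: list[PullbackBin] = []
    for flat in range(cover.n_cubes):
        idx = np.unravel_index(flat, (cover.r,) * cover.m)
        mask = masks[0][idx[0]].copy()
        for dim in range(1, cover.m):
            mask &= masks[dim][idx[dim]]
        members = np.flatnonzero(mask)
        if members.size:
            bins.append(PullbackBin(cube_index=tuple(int(i) for i in idx),
                                    members=tuple(int(i) for i in members)))
    covered = set()
    for b in bins:
        covered.update(b.members)
    if len(covered) != lens_image.n_obs:
        missing = set(range(lens_image.n_obs)) - covered
        raise AssertionError(f"cover failed to contain observations {sorted(missing)[:5]}")
    return bins


def partial_cluster(
    data: DataMatrix, bin_: PullbackBin, clusterer: str = "single_linkage_gap"
) -> list[tuple[int, ...]]:
    """Partition one bin's members by clustering on the original coordinates.

    The default clusterer is single-linkage agglomerative clustering cut at
    the first merge whose distance exceeds mean + 1 SD of all merge
    distances in the bin — a parameter-light gap heuristic.  Bins with at
    most two members, or with no significant gap, stay a single cluster.
    """
    members = np.asarray(bin_.members, dtype=int)
    if members.size == 0:
        raise ValueError("cannot cluster an empty bin")
    if clusterer != "single_linkage_gap":
        raise ValueError(f"unsupported clusterer {clusterer!r}")
    if members.size <= 2:
        return [tuple(int(i) for i in members)]
    points = data.values[members]
    dists = pdist(points)
    if not dists.any():  # all identical points
        return [tuple(int(i) for i in members)]
    link = linkage(dists, method="single")
    heights = link[:, 2]  # nondecreasing for single linkage
    gaps = np.diff(heights)
    threshold = heights.mean() + heights.std(ddof=0)
    big = np.flatnonzero(gaps > threshold)
    if big.size == 0:
        return [tuple(int(i) for i in members)]
    # cut inside the first outsized jump of the merge-height sequence
    first = big[0]
    cut = 0.5 * (heights[first] + heights[first + 1])
    labels = fcluster(link, t=cut, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for local, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(int(members[local]))
    return [tuple(v) for _, v in sorted(clusters.items())]


def build_mapper_graph(partial_clusters: list[tuple[tuple[int, ...], tuple[int, ...]]]) -> MapperGraph:
    """Assemble the Mapper graph from per-bin clusters.

    ``partial_clusters`` is a list of (cube_index, member tuple) pairs, one
    per within-bin cluster.  Distinct nodes are joined by an edge weighted
    by their shared-observation count; every node carries a self-loop of
    weight equal to its cardinality.
    """
    if not partial_clusters:
        raise ValueError("no clusters supplied")
    nodes = tuple(
        MapperNode(node_id=i, members=tuple(mem), cube_index=tuple(cube))
        for i, (cube, mem) in enumerate(partial_clusters)
    )
    # invert membership once; pairwise intersection via shared observations
    obs_to_nodes: dict[int, list[int]] = {}
    for node in nodes:
        for obs in node.members:
            obs_to_nodes.setdefault(obs, []).append(node.node_id)
    edges: dict[tuple[int, int], float] = {}
    for node in nodes:
        edges[(node.node_id, node.node_id)] = float(len(node.members))
    for node_list in obs_to_nodes.values():
        for i in range(len(node_list)):
            for j in range(i + 1, len(node_list)):
                a, b = node_list[i], node_list[j]
                key = (a, b) if a < b else (b, a)
                edges[key] = edges.get(key, 0.0) + 1.0
    return MapperGraph(nodes=nodes, edges=edges)


def mapper_graph_from_data(
    data: DataMatrix,
    lens: str = "pca2",
    r: int = 5,
    g: float = 0.3,
    clusterer: str = "single_linkage_gap",
    seed: int | None = None,
) -> tuple[MapperGraph, list[PullbackBin]]:
    """Convenience wrapper running lens -> cover -> pullback -> clustering."""
    image = apply_lens(data, lens=lens, seed=seed)
    cover = build_cover(image, r=r, g=g)
    bins = pullback(image, cover)
    clusters = []
    for b in bins:
        for mem in partial_cluster(data, b, clusterer=clusterer):
            clusters.append((b.cube_index, mem))
    return build_mapper_graph(clusters), bins
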