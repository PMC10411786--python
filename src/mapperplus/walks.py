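"""Random-walk graph partitioning: walk-likelihood reassignment (WLA),
weighted modularity, and the walk-likelihood community finder (WLCF).

WLA refines a given m-way partition of a weighted graph.  For each
community c it launches random walks of ``l_max`` steps from the community's
nodes and accumulates the expected number of visits V(n, c) each node n
receives.  Nodes are then reassigned in a Bayesian manner: node n joins the
community maximizing the posterior P(c | n) ∝ P(n | c) P(c), where
P(n | c) = V(n, c) / Σ_n' V(n', c) is the normalized visit frequency and the
prior P(c) is the fraction of total connectivity held by community c.  The
sweep repeats until the assignment is a fixed point.

WLCF discovers the number of communities: starting from a single community
it alternates (i) bifurcating each community by a seeded balanced split
refined with WLA on the induced subgraph, (ii) a global WLA refinement, and
(iii) greedy merging of community pairs while merging increases the weighted
Newman modularity Q.  The outer loop stops when the community count repeats.

Self-loops are first-class citizens throughout: a walker can stay put, the
diagonal contributes (once) to node connectivity, and modularity uses the
same convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "WeightedGraph",
    "AssignmentMatrix",
    "transition_matrix",
    "expected_visits",
    "wla",
    "modularity",
    "wlcf",
]


@dataclass
class WeightedGraph:
    """Symmetric non-negative weighted graph, self-loops allowed.

    ``adjacency`` is an n x n symmetric matrix (dense or scipy sparse);
    a self-loop of weight w appears once on the diagonal.  Connectivity of a
    node is its row sum.
    """

    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        a = self.adjacency
        if not sp.issparse(a):
            a = sp.csr_matrix(np.asarray(a, dtype=float))
        a = a.tocsr().astype(float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if (a.data < 0).any():
            raise ValueError("edge weights must be non-negative")
        if a.nnz and abs(a - a.T).max() > 1e-9:
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def connectivity(self) -> np.ndarray:
        """Weighted degree of each node (self-loop counted once)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def total_weight(self) -> float:
        """2W: the total of the adjacency matrix."""
        return float(self.adjacency.sum())

    @classmethod
    def from_edges(cls, n_nodes: int, edges: dict[tuple[int, int], float]) -> "WeightedGraph":
        """Build from an unordered-pair edge dict (as MapperGraph.edges)."""
        rows, cols, vals = [], [], []
        for (a, b), w in edges.items():
            rows.append(a)
            cols.append(b)
            vals.append(w)
            if a != b:
                rows.append(b)
                cols.append(a)
                vals.append(w)
        adj = sp.coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes))
        return cls(adjacency=adj.tocsr())

    @classmethod
    def from_mapper_graph(cls, mapper_graph) -> "WeightedGraph":
        return cls.from_edges(mapper_graph.n_nodes, mapper_graph.edges)


@dataclass
class AssignmentMatrix:
    """Binary N x m community-membership matrix U.

    Disjoint assignments have exactly one 1 per row; overlapping
    assignments have at least one.  Empty columns are disallowed.
    """

    u: np.ndarray
    disjoint: bool = field(default=True)

    def __post_init__(self) -> None:
        u = np.asarray(self.u)
        if u.ndim != 2:
            raise ValueError("U must be 2-D")
        u = (u != 0).astype(np.int8)
        sums = u.sum(axis=1)
        if self.disjoint:
            if not (sums == 1).all():
                raise ValueError("disjoint assignment requires each row to sum to 1")
        elif (sums < 1).any():
            raise ValueError("every observation must belong to >= 1 community")
        if (u.sum(axis=0) == 0).any():
            raise ValueError("empty community column present")
        self.u = u

    @property
    def n_obs(self) -> int:
        return self.u.shape[0]

    @property
    def m(self) -> int:
        return self.u.shape[1]

    def labels(self) -> np.ndarray:
        if not self.disjoint:
            raise ValueError("labels are defined only for disjoint assignments")
        return np.argmax(self.u, axis=1)

    @classmethod
    def from_labels(cls, labels, m: int | None = None) -> "AssignmentMatrix":
        """Build a disjoint assignment from integer labels, dropping gaps."""
        labels = np.asarray(labels, dtype=int)
        uniq = np.unique(labels)
        remap = {v: i for i, v in enumerate(uniq)}
        m_eff = len(uniq)
        u = np.zeros((len(labels), m_eff), dtype=np.int8)
        u[np.arange(len(labels)), [remap[v] for v in labels]] = 1
        return cls(u=u, disjoint=True)

    @classmethod
    def from_sets(cls, sets, n_obs: int) -> "AssignmentMatrix":
        """Build an overlapping assignment from a list of index sets."""
        u = np.zeros((n_obs, len(sets)), dtype=np.int8)
        for c, members in enumerate(sets):
            u[list(members), c] = 1
        return cls(u=u, disjoint=bool((u.sum(axis=1) == 1).all()))


def transition_matrix(graph: WeightedGraph, *, allow_isolated: bool = False) -> sp.csr_matrix:
    """Row-stochastic transition matrix T(u, v) = w(u, v) / connectivity(u).

    Isolated nodes (zero connectivity) are rejected unless
    ``allow_isolated`` — then their rows are all-zero (the walker vanishes),
    which is what internal induced-subgraph refinement needs.
    """
    k = graph.connectivity
    if (k <= 0).any():
        if not allow_isolated:
            raise ValueError("graph has isolated nodes (zero connectivity)")
        inv = np.zeros_like(k)
        inv[k > 0] = 1.0 / k[k > 0]
    else:
        inv = 1.0 / k
    return sp.diags(inv) @ graph.adjacency


def expected_visits(t: sp.csr_matrix, u: AssignmentMatrix, l_max: int) -> np.ndarray:
    """Expected per-walk visit counts V(n, c) for walks of l_max steps.

    V(n, c) is the mean over start nodes n' in community c of
    Σ_{l=1}^{l_max} [T^l](n', n), evaluated by iterated vector-matrix
    products (T^l is never materialized).
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    sizes = u.u.sum(axis=0).astype(float)
    start = (u.u.T / sizes[:, None]).astype(float)  # m x n rows: uniform on c
    acc = np.zeros_like(start)
    p = start
    t_c = t.T.tocsr()  # propagate via sparse @ dense to keep ndarray results
    for _ in range(l_max):
        p = (t_c @ p.T).T
        acc += p
    return acc.T


def _posterior(v: np.ndarray, u: AssignmentMatrix, connectivity: np.ndarray) -> np.ndarray:
    """Bayesian reassignment scores P(c | n) ∝ P(n | c) P(c).

    Single swap point for the update rule.  P(n | c) is the column-normalized
    visit matrix (the chance a community-c walker's next recorded visit is
    node n).  The prior over communities is uniform: V(n, c) is already a
    per-walk average, so community size does not inflate it, and weighting by
    community connectivity mass instead makes the largest community absorb
    nodes whose visit evidence is balanced, collapsing valid partitions.
    """
    col_mass = v.sum(axis=0)
    col_mass[col_mass == 0] = 1.0  # unreachable community: likelihood stays 0
    return v / col_mass


def wla(
    graph: WeightedGraph,
    u0: AssignmentMatrix,
    l_max: int | None = None,
    max_iter: int = 100,
    *,
    _allow_isolated: bool = False,
) -> tuple[AssignmentMatrix, bool]:
    """Walk-likelihood refinement of a disjoint partition.

    Returns (assignment, converged).  The result has at most m communities
    (empty ones are dropped) and is a fixed point of the reassignment rule
    unless ``max_iter`` was exhausted.  Ties in the posterior argmax break
    toward the lowest community index, making the run deterministic.
    """
    if not u0.disjoint:
        raise ValueError("WLA requires a disjoint initial assignment")
    if l_max is None:
        l_max = default_l_max(graph.n_nodes)
    if u0.m == 1:
        return u0, True
    t = transition_matrix(graph, allow_isolated=_allow_isolated)
    k = graph.connectivity
    labels = u0.labels()
    u = u0
    for _ in range(max_iter):
        v = expected_visits(t, u, l_max)
        post = _posterior(v, u, k)
        new_labels = np.argmax(post, axis=1)  # argmax ties -> lowest index
        if (new_labels == labels).all():
            return AssignmentMatrix.from_labels(labels), True
        labels = new_labels
        u = AssignmentMatrix.from_labels(labels)
        if u.m == 1:
            return u, True
    return AssignmentMatrix.from_labels(labels), False


def modularity(graph: WeightedGraph, u: AssignmentMatrix) -> float:
    """Weighted Newman modularity of a disjoint partition.

    Q = Σ_c [ W_in(c)/2W − (K_c/2W)^2 ] with W_in(c) the total adjacency
    weight inside community c (off-diagonal pairs counted in both orders,
    self-loops once), K_c the community's connectivity mass, and 2W the
    adjacency total.  Q = 0 for a single community; Q ∈ [−1, 1].
    """
    if not u.disjoint:
        raise ValueError("modularity requires a disjoint partition")
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    two_w = graph.total_weight
    if two_w == 0:
        raise ValueError("graph has no weight")
    uf = u.u.astype(float)
    e = uf.T @ (graph.adjacency @ uf)  # m x m community-aggregated weight
    k_c = uf.T @ graph.connectivity
    return float(np.trace(e) / two_w - ((k_c / two_w) ** 2).sum())


def default_l_max(n_nodes: int) -> int:
    """Logarithmic mixing horizon: ceil(log n) + 2."""
    return int(math.ceil(math.log(max(n_nodes, 2)))) + 2


def _greedy_merge(graph: WeightedGraph, u: AssignmentMatrix) -> AssignmentMatrix:
    """Merge the community pair with the largest positive ΔQ until none helps."""
    labels = u.labels().copy()
    uf = u.u.astype(float)
    e = np.asarray(uf.T @ (graph.adjacency @ uf))
    k = uf.T @ graph.connectivity
    two_w = graph.total_weight
    alive = list(range(u.m))
    while len(alive) > 1:
        best, best_dq = None, 0.0
        for ia, a in enumerate(alive):
            for b in alive[ia + 1:]:
                dq = 2.0 * (e[a, b] / two_w - k[a] * k[b] / two_w ** 2)
                if dq > best_dq:
                    best, best_dq = (a, b), dq
        if best is None:
            break
        a, b = best
        e[a, :] += e[b, :]
        e[:, a] += e[:, b]
        k[a] += k[b]
        labels[labels == b] = a
        alive.remove(b)
    return AssignmentMatrix.from_labels(labels)


def _bifurcate(
    graph: WeightedGraph,
    labels: np.ndarray,
    l_max: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Split every community in two by a random balanced cut refined by WLA
    on the community's induced subgraph."""
    new_labels = np.empty_like(labels)
    next_id = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            new_labels[idx] = next_id
            next_id += 1
            continue
        sub = WeightedGraph(adjacency=graph.adjacency[idx][:, idx])
        perm = rng.permutation(idx.size)
        half = idx.size // 2
        split = np.zeros(idx.size, dtype=int)
        split[perm[half:]] = 1
        refined, _ = wla(
            sub,
            AssignmentMatrix.from_labels(split),
            l_max=l_max,
            _allow_isolated=True,
        )
        sub_labels = refined.labels()
        new_labels[idx] = next_id + sub_labels
        next_id += int(sub_labels.max()) + 1
    return new_labels


def wlcf(
    graph: WeightedGraph,
    l_max: int | None = None,
    seed: int | None = None,
    max_outer: int = 20,
) -> tuple[AssignmentMatrix, bool]:
    """Walk-likelihood community finder: detect communities and their count.

    Alternates bifurcation (seeded balanced splits refined by WLA), global
    WLA refinement, and greedy modularity-increasing merging, until the
    community count is unchanged between consecutive outer iterations.
    Returns (assignment, converged).
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    if (graph.connectivity <= 0).any():
        raise ValueError("graph has isolated nodes (zero connectivity)")
    if l_max is None:
        l_max = default_l_max(graph.n_nodes)
    rng = np.random.default_rng(seed)
    labels = np.zeros(graph.n_nodes, dtype=int)
    if graph.n_nodes == 1:
        return AssignmentMatrix.from_labels(labels), True
    m_prev = -1
    for _ in range(max_outer):
        labels = _bifurcate(graph, labels, l_max, rng)
        refined, _ = wla(graph, AssignmentMatrix.from_labels(labels), l_max=l_max)
        merged = _greedy_merge(graph, refined)
        labels = merged.labels()
        m = merged.m
        if m == m_prev:
            return merged, True
        m_prev = m
    return AssignmentMatrix.from_labels(labels), False
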