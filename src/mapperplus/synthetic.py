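"""Seeded generators with planted ground truth for every input class the
pipeline consumes: separable point clouds, a noisy circle (a data loop),
graphs with planted community structure, and a mixed categorical/continuous
cohort with subgroup-linked binary outcome.

All generators are pure functions of their parameters and an integer seed:
the same call yields bit-identical output.  Planted labels are returned in a
form the agreement metrics consume directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .preprocess import CATEGORICAL, NUMERIC, RawTable
from .walks import WeightedGraph

__all__ = [
    "LabeledPointCloud",
    "gaussian_blobs",
    "noisy_circle",
    "planted_partition_graph",
    "mixed_cohort",
]


@dataclass(frozen=True)
class LabeledPointCloud:
    """Points in R^d with planted community labels and their provenance."""

    points: np.ndarray
    planted_labels: np.ndarray
    params: dict

    @property
    def n_obs(self) -> int:
        return self.points.shape[0]

    def to_data_matrix(self):
        from .preprocess import DataMatrix

        return DataMatrix(
            values=self.points,
            row_ids=np.arange(self.n_obs),
            col_names=tuple(f"x{j}" for j in range(self.points.shape[1])),
        )


def gaussian_blobs(
    n_per_blob: int, centers, sigma: float, seed: int
) -> LabeledPointCloud:
    """Isotropic Gaussian clouds around each center, labels by center."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] < 1:
        raise ValueError("at least one center required")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for c, center in enumerate(centers):
        parts.append(rng.normal(loc=center, scale=sigma, size=(n_per_blob, centers.shape[1])))
        labels.extend([c] * n_per_blob)
    return LabeledPointCloud(
        points=np.vstack(parts),
        planted_labels=np.array(labels, dtype=int),
        params={"n_per_blob": n_per_blob, "sigma": sigma, "seed": seed,
                "centers": centers.tolist()},
    )


def noisy_circle(n: int, radius: float, noise_sigma: float, seed: int) -> LabeledPointCloud:
    """Points on a circle with radial Gaussian noise; a single planted label.

    Exercises the loop topology a Mapper graph should capture as a cycle.
    """
    if n < 8:
        raise ValueError("need at least 8 points for a circle")
    rng = np.random.default_rng(seed)
    theta = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n))
    radii = radius + rng.normal(0.0, noise_sigma, size=n) if noise_sigma > 0 else np.full(n, radius)
    points = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    return LabeledPointCloud(
        points=points,
        planted_labels=np.zeros(n, dtype=int),
        params={"n": n, "radius": radius, "noise_sigma": noise_sigma, "seed": seed},
    )


def planted_partition_graph(
    block_sizes, p_in: float, p_out: float, seed: int
) -> tuple[WeightedGraph, np.ndarray]:
    """Unit-weight planted-partition (stochastic block model) graph.

    Within-block edges appear with probability ``p_in``, between-block edges
    with ``p_out`` < ``p_in``.  A node left isolated by the draw is rewired
    to one random within-block neighbor so the graph satisfies the
    walk-partitioning connectivity contract.
    """
    block_sizes = [int(b) for b in block_sizes]
    if any(b < 1 for b in block_sizes):
        raise ValueError("empty block")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    n = labels.size
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                rows.append(i)
                cols.append(j)
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    adj = (adj + adj.T).tolil()
    degree = np.asarray(adj.sum(axis=1)).ravel()
    for i in np.flatnonzero(degree == 0):
        mates = np.flatnonzero((labels == labels[i]) & (np.arange(n) != i))
        if mates.size == 0:  # singleton block: attach a self-loop
            adj[i, i] = 1.0
            continue
        j = int(rng.choice(mates))
        adj[i, j] = 1.0
        adj[j, i] = 1.0
    return WeightedGraph(adjacency=adj.tocsr()), labels


def mixed_cohort(
    n: int,
    n_numeric: int,
    n_categorical: int,
    n_groups: int,
    effect: float,
    outcome_gap: float,
    seed: int,
) -> tuple[RawTable, np.ndarray, np.ndarray]:
    """Synthetic mixed-type cohort with planted subgroups and a linked
    binary outcome: a stand-in for a clinical table with continuous
    measurements, categorical codes and subgroup-dependent survival.

    Numeric features are unit-variance Gaussians whose group means are
    shifted by ``effect`` standard deviations; categorical features are
    group-biased multinomials over three levels; the binary outcome has
    success probability stepped by ``outcome_gap`` between consecutive
    groups around a base rate of 0.5.  Returns (table, group labels,
    outcomes).
    """
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if effect < 0:
        raise ValueError("effect must be non-negative")
    rng = np.random.default_rng(seed)
    groups = rng.integers(0, n_groups, size=n)
    cols: dict[str, np.ndarray] = {}
    tags: dict[str, str] = {}
    for j in range(n_numeric):
        # group means spaced effect*sigma apart, group order shuffled per
        # feature so no single feature carries all of the separation
        offsets = rng.permutation(n_groups) - (n_groups - 1) / 2.0
        cols[f"num{j}"] = rng.standard_normal(n) + effect * offsets[groups]
        tags[f"num{j}"] = NUMERIC
    levels = np.array(["A", "B", "C"])
    for j in range(n_categorical):
        base = rng.dirichlet(np.full(3, 3.0), size=n_groups)
        if effect > 0:
            # each group leans toward a preferred level; the lean is kept
            # moderate so categorical codes inform but do not dominate the
            # numeric separation (as in real cohort tables)
            pref = rng.integers(0, 3, size=n_groups)
            for gidx in range(n_groups):
                base[gidx, pref[gidx]] += 1.0
            base = base / base.sum(axis=1, keepdims=True)
        draws = np.array(
            [rng.choice(3, p=base[gidx]) for gidx in groups]
        )
        cols[f"cat{j}"] = levels[draws]
        tags[f"cat{j}"] = CATEGORICAL
    centered = groups - (n_groups - 1) / 2.0
    p_success = np.clip(0.5 + outcome_gap * centered, 0.02, 0.98)
    outcome = (rng.random(n) < p_success).astype(int)
    frame = pd.DataFrame(cols, index=pd.RangeIndex(n, name="row_id"))
    return RawTable(frame=frame, tags=tags), groups, outcome
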