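"""Normalized mutual information and the (resolution, gain) stability grid.

NMI compares two disjoint clusterings U (N x m) and U' (N x m') through the
membership probabilities

    P_U(c)      = (1/N) Σ_i U_ic
    P_UU'(c,c') = (1/N) Σ_i U_ic U'_ic'
    I(U, U')    = Σ_c Σ_c' P_UU'(c,c') log[ P_UU'(c,c') / (P_U(c) P_U'(c')) ]
    NMI(U, U')  = 2 I(U, U') / ( I(U, U) + I(U', U') ),

with natural logarithms and 0·log(0/x) = 0.  I(U, U) is the Shannon entropy
of U, so NMI is 1 iff the clusterings are identical and 0 when the joint
membership factorizes (mutually random clusterings).

The stability grid is the parameter-selection device: run the full pipeline
at every (r, g) on a grid and score each cell by the mean NMI between its
clustering and those of the (up to 8) adjacent cells.  Cells on a high
plateau are parameter choices whose clustering is insensitive to small
perturbations of r and g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .preprocess import DataMatrix
from .walks import AssignmentMatrix

__all__ = ["mutual_information", "nmi", "stability_grid", "StabilityGrid"]


def _as_assignment(u) -> AssignmentMatrix:
    if isinstance(u, AssignmentMatrix):
        return u
    return AssignmentMatrix.from_labels(np.asarray(u))


def mutual_information(u, uprime) -> float:
    """Mutual information I(U, U') in nats between two disjoint clusterings."""
    u = _as_assignment(u)
    uprime = _as_assignment(uprime)
    if u.n_obs != uprime.n_obs:
        raise ValueError("clusterings cover different numbers of observations")
    if not (u.disjoint and uprime.disjoint):
        raise ValueError("mutual information requires disjoint clusterings")
    n = u.n_obs
    joint = (u.u.astype(float).T @ uprime.u.astype(float)) / n
    p = u.u.sum(axis=0) / n
    q = uprime.u.sum(axis=0) / n
    outer = np.outer(p, q)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / outer[mask])))


def nmi(u, uprime) -> float:
    """Normalized mutual information in [0, 1]; symmetric; 1 iff identical.

    Raises when both clusterings are trivial (m = m' = 1): the normalizer
    I(U,U) + I(U',U') is then zero and the score undefined.
    """
    u = _as_assignment(u)
    uprime = _as_assignment(uprime)
    denom = mutual_information(u, u) + mutual_information(uprime, uprime)
    if denom <= 0:
        raise ValueError("NMI undefined: both clusterings are a single cluster")
    return 2.0 * mutual_information(u, uprime) / denom


@dataclass
class StabilityGrid:
    """Pipeline clusterings over an (r, g) grid with neighbor-agreement scores.

    ``cells[(r, g)]`` holds the assignment, the detected cluster count, the
    mean NMI against the adjacent cells and a failure marker; every cell was
    produced by an identical configuration except (r, g).
    """

    axis_r: tuple[int, ...]
    axis_g: tuple[float, ...]
    cells: dict[tuple[int, float], dict[str, Any]] = field(default_factory=dict)

    def passing(self, threshold: float) -> list[tuple[int, float]]:
        """Cells whose mean-neighbor score exceeds a caller-chosen threshold.

        The threshold is deliberately a required argument: what counts as
        "stable enough" depends on the dataset.
        """
        return [
            key
            for key, cell in sorted(self.cells.items())
            if cell.get("mean_neighbor_nmi") is not None
            and cell["mean_neighbor_nmi"] >= threshold
        ]

    def to_frame(self):
        import pandas as pd

        rows = []
        for (r, g), cell in sorted(self.cells.items()):
            rows.append(
                {
                    "r": r,
                    "g": g,
                    "m_detected": cell.get("m_detected"),
                    "mean_neighbor_nmi": cell.get("mean_neighbor_nmi"),
                    "failed": cell.get("failed", False),
                }
            )
        return pd.DataFrame(rows)


def stability_grid(
    data: DataMatrix,
    r_values,
    g_values,
    lens: str = "pca2",
    clusterer: str = "single_linkage_gap",
    l_max: int | None = None,
    seed: int | None = 0,
) -> StabilityGrid:
    """Run the full pipeline at every (r, g) and score neighbor agreement.

    Every cell reuses the one seed so that differences between cells reflect
    (r, g) only.  Edge and corner cells average over their existing
    neighbors (5 and 3 respectively); a failed cell is skipped by its
    neighbors and carries no score.  Trivial single-cluster pairs, for which
    NMI is undefined, are scored as agreement 1 when both cells are trivial.
    """
    from .instances import run_pipeline

    r_values = tuple(int(r) for r in r_values)
    g_values = tuple(float(g) for g in g_values)
    grid = StabilityGrid(axis_r=r_values, axis_g=g_values)
    for r in r_values:
        for g in g_values:
            cell: dict[str, Any] = {}
            try:
                res = run_pipeline(
                    data, lens=lens, resolution=r, gain=g,
                    clusterer=clusterer, l_max=l_max, seed=seed,
                )
                cell["assignment"] = res.assignment
                cell["m_detected"] = res.assignment.m
                cell["failed"] = False
            except Exception as exc:  # noqa: BLE001 - grid cells fail independently
                cell["failed"] = True
                cell["error"] = str(exc)
            grid.cells[(r, g)] = cell
    for i, r in enumerate(r_values):
        for j, g in enumerate(g_values):
            cell = grid.cells[(r, g)]
            if cell["failed"]:
                cell["mean_neighbor_nmi"] = None
                continue
            scores = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if not (0 <= ni < len(r_values) and 0 <= nj < len(g_values)):
                        continue
                    other = grid.cells[(r_values[ni], g_values[nj])]
                    if other["failed"]:
                        continue
                    scores.append(_pair_score(cell["assignment"], other["assignment"]))
            cell["mean_neighbor_nmi"] = float(np.mean(scores)) if scores else None
    return grid


def _pair_score(a: AssignmentMatrix, b: AssignmentMatrix) -> float:
    if a.m == 1 and b.m == 1:
        return 1.0  # both trivial: identical clusterings
    if a.m == 1 or b.m == 1:
        # one trivial: no shared structure beyond the trivial split
        return nmi(a, b) if max(a.m, b.m) > 1 else 1.0
    return nmi(a, b)
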