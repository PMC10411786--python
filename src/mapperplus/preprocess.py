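"""Tabular input handling: type-tagged tables, frequency encoding, z-scoring.

Clinical cohort tables mix continuous measurements with categorical codes.
Before the topological pipeline can treat the table as a metric space, every
column must be numeric and on a comparable scale: categorical columns are
replaced by the relative frequency of each level (frequency encoding) and all
columns are then standardized to z-scores.  The metric on the resulting
matrix is Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawTable",
    "DataMatrix",
    "read_table",
    "frequency_encode",
    "zscore",
    "write_labels",
    "read_labels",
]

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass
class RawTable:
    """A table of observations with per-column type tags.

    Parameters
    ----------
    frame
        One row per observation, one column per feature.  The index holds
        stable row identifiers.
    tags
        Mapping from column name to ``"numeric"`` or ``"categorical"``.
        Tags must cover every column exactly.
    """

    frame: pd.DataFrame
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frame) < 1:
            raise ValueError("table must contain at least one observation")
        cols = list(self.frame.columns)
        unknown = set(self.tags) - set(cols)
        if unknown:
            raise ValueError(f"schema names unknown columns: {sorted(unknown)}")
        for c in cols:
            self.tags.setdefault(c, _infer_tag(self.frame[c]))
        bad = {c: t for c, t in self.tags.items() if t not in (NUMERIC, CATEGORICAL)}
        if bad:
            raise ValueError(f"invalid column tags: {bad}")

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def row_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()


@dataclass(frozen=True)
class DataMatrix:
    """Fully numeric N x d matrix with stable row identifiers.

    This is the metric space the Mapper construction operates on; the metric
    is Euclidean distance on ``values``.
    """

    values: np.ndarray
    row_ids: np.ndarray
    col_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.isfinite(v).all():
            raise ValueError("matrix contains non-finite values")
        if len(self.row_ids) != v.shape[0] or len(self.col_names) != v.shape[1]:
            raise ValueError("row_ids/col_names lengths do not match values shape")
        object.__setattr__(self, "values", v)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _infer_tag(col: pd.Series) -> str:
    return NUMERIC if pd.api.types.is_numeric_dtype(col) else CATEGORICAL


def read_table(
    path,
    schema: dict[str, str] | None = None,
    *,
    id_column: str | None = None,
    sep: str | None = None,
    drop_missing: bool = False,
) -> RawTable:
    """Read a delimited text file with a header row into a :class:`RawTable`.

    Column types are inferred from dtypes (non-numeric implies categorical)
    unless forced by ``schema``.  Missing values are rejected unless
    ``drop_missing`` is set, in which case rows with any missing entry are
    removed first; imputation is deliberately out of scope.
    """
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if id_column is not None:
        if id_column not in frame.columns:
            raise ValueError(f"id column {id_column!r} not in table")
        frame = frame.set_index(id_column)
    if drop_missing:
        frame = frame.dropna(axis=0)
        if len(frame) == 0:
            raise ValueError("all rows removed by the missing-value filter")
    if frame.isna().any().any():
        raise ValueError(
            "table contains missing values; pass drop_missing=True to remove "
            "the affected rows"
        )
    tags = dict(schema) if schema else {}
    # schema-forced categorical columns keep their printed representation
    for c, t in tags.items():
        if t == CATEGORICAL and c in frame.columns:
            frame[c] = frame[c].astype(str)
        elif t == NUMERIC and c in frame.columns:
            frame[c] = pd.to_numeric(frame[c])
    return RawTable(frame=frame, tags=tags)


def frequency_encode(table: RawTable) -> RawTable:
    """Replace every categorical column by per-level relative frequencies.

    Each category value maps to (count of that value in the column) / N,
    computed independently per column.  Numeric columns pass through
    untouched; the result carries only numeric tags.
    """
    frame = table.frame.copy()
    n = len(frame)
    tags: dict[str, str] = {}
    for c in frame.columns:
        if table.tags[c] == CATEGORICAL:
            freq = frame[c].value_counts() / n
            frame[c] = frame[c].map(freq).astype(float)
        tags[c] = NUMERIC
    return RawTable(frame=frame, tags=tags)


def zscore(table: RawTable) -> DataMatrix:
    """Standardize every column to mean 0, sample (n-1) SD 1.

    Constant columns (zero variance) map to all-zeros rather than dividing
    by zero.  All columns must already be numeric; run
    :func:`frequency_encode` first for mixed tables.
    """
    non_numeric = [c for c, t in table.tags.items() if t != NUMERIC]
    if non_numeric:
        raise ValueError(f"non-numeric columns present: {non_numeric}")
    values = table.frame.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    centered = values - mean
    if values.shape[0] > 1:
        sd = values.std(axis=0, ddof=1)
    else:
        sd = np.zeros(values.shape[1])
    out = np.zeros_like(centered)
    nonconst = sd > 0
    out[:, nonconst] = centered[:, nonconst] / sd[nonconst]
    return DataMatrix(
        values=out,
        row_ids=table.row_ids,
        col_names=tuple(str(c) for c in table.frame.columns),
    )


def preprocess(table: RawTable) -> DataMatrix:
    """Frequency-encode then z-score: the standard preparation step."""
    return zscore(frequency_encode(table))


def write_labels(assignment, row_ids, path) -> None:
    """Write a disjoint clustering as a (row_id, cluster) CSV.

    Clusters are renumbered 0..m-1 in decreasing size order, ties broken by
    first appearance, so the file is canonical regardless of the internal
    label values.
    """
    from .walks import AssignmentMatrix

    if isinstance(assignment, AssignmentMatrix):
        if not assignment.disjoint:
            raise ValueError("overlapping assignment passed to the disjoint writer")
        labels = assignment.labels()
    else:
        labels = np.asarray(assignment, dtype=int)
    labels = canonical_labels(labels)
    pd.DataFrame({"row_id": np.asarray(row_ids), "cluster": labels}).to_csv(
        path, index=False
    )


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..m-1 by decreasing size, ties by first appearance."""
    labels = np.asarray(labels, dtype=int)
    uniq, first, counts = np.unique(labels, return_index=True, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], first[i]))
    remap = {uniq[i]: rank for rank, i in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=int)


def read_labels(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a labels CSV back as (row_ids, cluster labels)."""
    frame = pd.read_csv(path)
    return frame["row_id"].to_numpy(), frame["cluster"].to_numpy(dtype=int)
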