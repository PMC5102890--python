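"""Shared containers: partitions, similarity matrices, benchmark instances."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import InvalidConditionError

__all__ = [
    "MatrixType",
    "Partition",
    "SimilarityMatrix",
    "TimeSeriesData",
    "BenchmarkInstance",
]

_SYM_TOL = 1e-10


class MatrixType(str, enum.Enum):
    CORRELATION = "correlation"
    REFLECTED_EUCD = "reflected_eucd"
    COUNT = "count"


@dataclass(frozen=True)
class Partition:
    """A node -> community labeling with labels contiguous from 1.

    ``labels[i]`` is the community of node ``i``.  Construction canonicalizes
    arbitrary hashable labels to 1..K in order of first appearance, so planted
    and recovered partitions are always directly comparable.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        _, canonical = np.unique(arr, return_inverse=True)
        # re-map to order of first appearance, 1-based
        first_seen: dict[int, int] = {}
        out = np.empty(arr.size, dtype=np.int64)
        for i, lab in enumerate(canonical):
            if lab not in first_seen:
                first_seen[lab] = len(first_seen) + 1
            out[i] = first_seen[lab]
        object.__setattr__(self, "labels", out)

    @property
    def n_nodes(self) -> int:
        return int(self.labels.size)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())

    def sizes(self) -> np.ndarray:
        """Community sizes, indexed by community label - 1."""
        return np.bincount(self.labels - 1, minlength=self.n_communities)

    @classmethod
    def from_sizes(cls, sizes) -> "Partition":
        """Blocked partition: the first ``sizes[0]`` nodes form community 1, ..."""
        return cls(np.repeat(np.arange(1, len(sizes) + 1), sizes))

    def __eq__(self, other) -> bool:  # canonical labels -> exact comparison
        return isinstance(other, Partition) and np.array_equal(
            self.labels, other.labels
        )


@dataclass
class SimilarityMatrix:
    """A symmetric weighted matrix with a zero diagonal.

    ``matrix_type`` records the family (count / correlation / reflected
    Euclidean distance); ``diagonal_zeroed`` flags that the self-similarity
    entries were removed, the final construction step before detection.
    """

    values: np.ndarray
    matrix_type: MatrixType
    diagonal_zeroed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("similarity matrix contains non-finite values")
        if np.max(np.abs(v - v.T)) > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")
        v = (v + v.T) / 2.0
        if self.diagonal_zeroed:
            np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TimeSeriesData:
    """n_nodes x t_obs multivariate time series with its planted partition."""

    values: np.ndarray
    assignment: Partition
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series must be 2-D (nodes x time)")
        if v.shape[0] != self.assignment.n_nodes:
            raise InvalidConditionError("time series rows must match partition size")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def t_obs(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BenchmarkInstance:
    """One generated benchmark: matrix + planted truth + provenance."""

    matrix: SimilarityMatrix
    truth: Partition
    condition_id: int
    matrix_type: MatrixType
    replicate: int
    seed: int

    def __post_init__(self) -> None:
        if self.truth.n_nodes != self.matrix.n_nodes:
            raise InvalidConditionError("truth partition must cover every node")
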