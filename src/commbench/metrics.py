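"""Partition-recovery scores.

Four indices quantify how well a recovered partition matches the planted one:

* :func:`weighted_modularity` — Newman–Girvan modularity generalized to
  weighted graphs, ``Q_w = (1/2w) * sum_ij (w_ij - w_i w_j / 2w) delta(s_i, s_j)``
  where ``2w`` is the total edge strength and ``w_i`` a node's strength.
* :func:`majority_placement` — the fraction of nodes placed with at least half
  of their true community (high sensitivity, but inflated by merged
  "super communities").
* :func:`ari_ha` — the Hubert–Arabie adjusted Rand index, computed from the
  pair counts (a, b, c, d); chance-corrected, maximum 1.
* :func:`modularity_ratio` — recovered modularity over planted modularity,
  used to probe whether modularity alone signals accurate recovery.

:func:`cohens_d` gives the pooled-SD effect size used for post-hoc
method-vs-method contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._exceptions import UndefinedMetricError
from .types import Partition, SimilarityMatrix

__all__ = [
    "PairCounts",
    "EvalRecord",
    "pair_counts",
    "weighted_modularity",
    "majority_placement",
    "ari_ha",
    "modularity_ratio",
    "cohens_d",
]


@dataclass(frozen=True)
class PairCounts:
    """Node-pair agreement counts between two partitions.

    a: together in both; b: together in truth only; c: together in recovered
    only; d: apart in both.  They always sum to N*(N-1)/2.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EvalRecord:
    """One scored (condition, replicate, matrix type, method, run) cell."""

    condition_id: int
    matrix_type: str
    method: str
    replicate: int
    run_index: int
    seed: int
    mp: float
    ari: float
    q_recovered: float
    q_true: float
    mr: Optional[float]
    n_communities_found: int


def _as_matrix(matrix) -> np.ndarray:
    if isinstance(matrix, SimilarityMatrix):
        return matrix.values
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    return m


def _check_same_nodes(truth: Partition, recovered: Partition) -> None:
    if truth.n_nodes != recovered.n_nodes:
        raise ValueError(
            f"partitions cover different node sets "
            f"({truth.n_nodes} vs {recovered.n_nodes} nodes)"
        )


def weighted_modularity(matrix, partition: Partition) -> float:
    """Weighted modularity Q_w of ``partition`` on a nonnegative matrix.

    The sum runs over all ordered node pairs; the diagonal must be zero and
    negative weights must have been clipped beforehand (the scorer sees the
    same nonnegative matrix most detection methods see).
    """
    w = _as_matrix(matrix)
    if np.any(w < 0):
        raise ValueError("weighted_modularity expects nonnegative weights")
    if w.shape[0] != partition.n_nodes:
        raise ValueError("matrix and partition sizes differ")
    two_w = float(w.sum())
    if two_w == 0.0:
        raise UndefinedMetricError("modularity undefined for an all-zero matrix")
    strength = w.sum(axis=1)
    labels = partition.labels
    q = 0.0
    for c in range(1, partition.n_communities + 1):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() - strength[idx].sum() ** 2 / two_w
    return q / two_w


def pair_counts(truth: Partition, recovered: Partition) -> PairCounts:
    """Pair counts (a, b, c, d) from the truth x recovered contingency table."""
    _check_same_nodes(truth, recovered)
    n = truth.n_nodes
    cont = np.zeros((truth.n_communities, recovered.n_communities), dtype=np.int64)
    np.add.at(cont, (truth.labels - 1, recovered.labels - 1), 1)

    def comb2(x):
        return x * (x - 1) // 2

    a = int(comb2(cont).sum())
    same_truth = int(comb2(cont.sum(axis=1)).sum())
    same_rec = int(comb2(cont.sum(axis=0)).sum())
    b = same_truth - a
    c = same_rec - a
    d = comb2(n) - a - b - c
    return PairCounts(a, b, c, d)


def ari_ha(truth: Partition, recovered: Partition) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions of one node set."""
    pc = pair_counts(truth, recovered)
    if truth.n_nodes < 2:
        raise ValueError("ARI requires at least two nodes")
    n2 = pc.total
    cross = (pc.a + pc.b) * (pc.a + pc.c) + (pc.c + pc.d) * (pc.b + pc.d)
    num = n2 * (pc.a + pc.d) - cross
    den = n2 * n2 - cross
    if den == 0:  # both partitions trivial (all-singletons vs one community edge case)
        return 1.0 if num == 0 else 0.0
    return num / den


def majority_placement(truth: Partition, recovered: Partition) -> float:
    """Fraction of nodes whose recovered community holds >= 50% of their true one.

    The membership fraction is computed over the full true community,
    including the node itself.  Note the deliberate asymmetry: merging all
    nodes into one super community scores MP = 1 while ARI drops to ~0.
    """
    _check_same_nodes(truth, recovered)
    cont = np.zeros((truth.n_communities, recovered.n_communities), dtype=np.int64)
    np.add.at(cont, (truth.labels - 1, recovered.labels - 1), 1)
    true_sizes = cont.sum(axis=1)
    # tau_i depends only on (true community, recovered community) of node i
    frac = cont / true_sizes[:, None]
    tau_cell = frac >= 0.5
    correct = int(cont[tau_cell].sum())
    return correct / truth.n_nodes


def modularity_ratio(matrix, truth: Partition, recovered: Partition) -> float:
    """MR = Q(recovered) / Q(planted).  Undefined when the planted Q is zero.

    MR is deliberately not clamped: a recovered partition can out-score the
    planted one, giving MR > 1.
    """
    q_true = weighted_modularity(matrix, truth)
    if q_true == 0.0:
        raise UndefinedMetricError(
            "modularity ratio undefined: planted partition has zero modularity"
        )
    q_rec = weighted_modularity(matrix, recovered)
    return q_rec / q_true


def cohens_d(group_i, group_j) -> float:
    """Cohen's d between two score samples using the pooled standard deviation."""
    x = np.asarray(group_i, dtype=float)
    y = np.asarray(group_j, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    ni, nj = x.size, y.size
    pooled_var = ((ni - 1) * x.var(ddof=1) + (nj - 1) * y.var(ddof=1)) / (ni + nj - 2)
    if pooled_var == 0.0:
        raise UndefinedMetricError("Cohen's d undefined: zero pooled variance")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))
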