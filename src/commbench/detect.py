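"""The six weighted community detection algorithms under one contract.

Each method is an sklearn-style clusterer: ``fit(X)`` takes a symmetric
weighted matrix (ndarray or :class:`~commbench.types.SimilarityMatrix`) with a
zero diagonal and sets ``labels_`` (community labels canonicalized to 1..K by
first appearance) and ``n_communities_``.

Preprocessing convention: every method except the signed Louvain requires
nonnegative weights, so negative entries (from sampled correlations) are
clipped to zero at fit time; the signed Louvain consumes the signed matrix
unchanged.  Count matrices pass through untouched either way.

Algorithm internals delegate to python-igraph (leading eigenvector, Walktrap
with walk length 4, greedy modularity agglomeration, label propagation, and
the map-equation Infomap), matching the implementations practitioners use.
The signed Louvain is implemented here: mainstream libraries lack the
Gomez–Jensen–Arenas signed modularity, in which positive-subnetwork
modularity is rewarded and negative-subnetwork modularity penalized.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Optional

import igraph as ig
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from ._exceptions import DegenerateInputError
from ._seeds import STREAM_DETECT, derive_seed
from .types import MatrixType, Partition, SimilarityMatrix

__all__ = [
    "MethodSpec",
    "DetectionResult",
    "METHODS",
    "METHOD_NAMES",
    "NewmanSpectral",
    "Walktrap",
    "FastModularity",
    "SignedLouvain",
    "LabelPropagation",
    "Infomap",
    "preprocess",
    "run_method",
    "run_repeated",
]

# igraph draws from Python's global random module; deterministic methods are
# run under a fixed seed so repeated fits are bitwise identical.
_DETERMINISTIC_SEED = 20161110


def _matrix_values(X) -> np.ndarray:
    if isinstance(X, SimilarityMatrix):
        return X.values
    m = np.asarray(X, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if np.max(np.abs(m - m.T)) > 1e-10:
        raise ValueError("matrix must be symmetric")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


def _clip_negative(w: np.ndarray) -> np.ndarray:
    return np.clip(w, 0.0, None)


def _to_igraph(w: np.ndarray) -> ig.Graph:
    """Weighted undirected igraph from a dense nonnegative matrix (fast path)."""
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    vals = w[iu]
    mask = vals != 0.0
    edges = np.column_stack((iu[0][mask], iu[1][mask]))
    g = ig.Graph(n, edges.tolist())
    g.es["weight"] = vals[mask]
    return g


class BaseCommunityDetector(ClusterMixin, BaseEstimator):
    """Shared fit contract for the six detection methods."""

    method_name: str = ""
    deterministic: bool = True
    accepts_negative_weights: bool = False

    def __init__(self, random_state: Optional[int] = None):
        self.random_state = random_state

    def fit(self, X, y=None):
        w = _matrix_values(X)
        if not self.accepts_negative_weights:
            w = _clip_negative(w)
        if not np.any(w):
            raise DegenerateInputError(
                f"{self.method_name}: matrix is all zero after preprocessing; "
                "every node is isolated"
            )
        seed = self.random_state if not self.deterministic else None
        membership = self._detect(w, seed)
        part = Partition(np.asarray(membership))
        self.labels_ = part.labels
        self.n_communities_ = part.n_communities
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def _detect(self, w: np.ndarray, seed: Optional[int]) -> np.ndarray:
        raise NotImplementedError

    # --- helpers -----------------------------------------------------------
    def _seeded(self, seed: Optional[int]) -> None:
        random.seed(_DETERMINISTIC_SEED if seed is None else int(seed))


class NewmanSpectral(BaseCommunityDetector):
    """Newman's leading-eigenvector spectral bisection (no KL fine-tuning).

    Iteratively splits groups along the sign of the principal eigenvector of
    the (generalized) modularity matrix B = W - k k'/2w, accepting a split
    only while it increases modularity.  Implemented with a dense symmetric
    eigensolver so repeated runs are bitwise identical (ARPACK-based
    implementations carry mutable state across calls).
    """

    method_name = "NSA"
    deterministic = True

    def _detect(self, w, seed):
        n = w.shape[0]
        two_w = w.sum()
        k = w.sum(axis=1)
        b = w - np.outer(k, k) / two_w
        queue = [np.arange(n)]
        next_label = 1
        out = np.zeros(n, dtype=np.int64)
        while queue:
            idx = queue.pop()
            if idx.size == 1:
                out[idx] = next_label
                next_label += 1
                continue
            bg = b[np.ix_(idx, idx)].copy()
            bg[np.diag_indices_from(bg)] -= bg.sum(axis=1)
            vals, vecs = np.linalg.eigh(bg)
            v = vecs[:, -1]
            # near-zero components (degenerate leading eigenspace) go with the
            # positive side instead of being split by numerical noise
            tol = 1e-9 * max(np.abs(v).max(), 1e-300)
            s = np.where(v >= -tol, 1.0, -1.0)
            delta_q = s @ bg @ s / (2.0 * two_w)
            if vals[-1] <= 1e-12 or delta_q <= 1e-12 or np.all(s == s[0]):
                out[idx] = next_label  # indivisible subgraph
                next_label += 1
                continue
            queue.append(idx[s > 0])
            queue.append(idx[s < 0])
        return out


class Walktrap(BaseCommunityDetector):
    """Random-walk distance agglomeration with a modularity-selected cut."""

    method_name = "Walktrap"
    deterministic = True

    def __init__(self, random_state: Optional[int] = None, steps: int = 4):
        super().__init__(random_state=random_state)
        self.steps = steps

    def _detect(self, w, seed):
        self._seeded(seed)
        g = _to_igraph(w)
        dendro = g.community_walktrap(weights="weight", steps=self.steps)
        return dendro.as_clustering().membership


class FastModularity(BaseCommunityDetector):
    """Greedy modularity agglomeration (CNM fast modularity)."""

    method_name = "FastModularity"
    deterministic = True

    def _detect(self, w, seed):
        self._seeded(seed)
        g = _to_igraph(w)
        dendro = g.community_fastgreedy(weights="weight")
        return dendro.as_clustering().membership


class LabelPropagation(BaseCommunityDetector):
    """Majority-label iteration from random initial labels (seeded)."""

    method_name = "LabelPropagation"
    deterministic = False

    def _detect(self, w, seed):
        self._seeded(seed)
        g = _to_igraph(w)
        cl = g.community_label_propagation(weights="weight")
        return cl.membership


class Infomap(BaseCommunityDetector):
    """Map-equation minimization (Infomap), seeded."""

    method_name = "Infomap"
    deterministic = False

    def _detect(self, w, seed):
        self._seeded(seed)
        g = _to_igraph(w)
        cl = g.community_infomap(edge_weights="weight")
        return cl.membership


class SignedLouvain(BaseCommunityDetector):
    """Louvain optimization of signed (GJA) modularity; keeps negative weights.

    The objective splits the matrix into positive and negative subnetworks,

        Q = c+ * sum_c [W+_in(c) - S+(c)^2 / 2w+]
          - c- * sum_c [W-_in(c) - S-(c)^2 / 2w-]

    with ``objective='gja'`` using c+ = c- = 1/(2w+ + 2w-) and
    ``objective='sta'`` the asymmetric weighting c+ = 1/2w+,
    c- = 1/(2w+ + 2w-).  Optimization is the usual two-phase Louvain: local
    node moves in random order, then community aggregation, repeated until no
    move improves Q.
    """

    method_name = "LouvainGJA"
    deterministic = False
    accepts_negative_weights = True

    def __init__(
        self,
        random_state: Optional[int] = None,
        objective: str = "gja",
        tol: float = 1e-12,
    ):
        super().__init__(random_state=random_state)
        self.objective = objective
        self.tol = tol

    # -- objective ----------------------------------------------------------
    @staticmethod
    def _coeffs(twp: float, twn: float, objective: str) -> tuple[float, float]:
        tot = twp + twn
        if tot == 0:
            raise DegenerateInputError("all-zero matrix")
        if objective == "gja":
            return 1.0 / tot, 1.0 / tot
        if objective == "sta":
            return (1.0 / twp if twp else 0.0), 1.0 / tot
        if objective == "smp":
            return (1.0 / twp if twp else 0.0), (1.0 / twn if twn else 0.0)
        raise ValueError(f"unknown signed-modularity objective {objective!r}")

    def signed_modularity(self, w: np.ndarray, labels: np.ndarray) -> float:
        """Signed modularity of an integer labeling on the signed matrix ``w``."""
        w = _matrix_values(w) if not isinstance(w, np.ndarray) else w
        wp = np.clip(w, 0.0, None)
        wn = np.clip(-w, 0.0, None)
        twp, twn = wp.sum(), wn.sum()
        cp, cn = self._coeffs(twp, twn, self.objective)
        q = 0.0
        for lab in np.unique(labels):
            idx = labels == lab
            if twp:
                q += cp * (wp[np.ix_(idx, idx)].sum() - wp[idx].sum() ** 2 / twp)
            if twn:
                q -= cn * (wn[np.ix_(idx, idx)].sum() - wn[idx].sum() ** 2 / twn)
        return q

    # -- optimization -------------------------------------------------------
    def _one_level(self, wp, wn, cp, cn, twp, twn, rng):
        n = wp.shape[0]
        comm = np.arange(n)
        kp = wp.sum(axis=1)
        kn = wn.sum(axis=1)
        sp = kp.copy()
        sn = kn.copy()
        moved_any = False
        for _ in range(200):  # sweeps until stable
            moved = 0
            for i in rng.permutation(n):
                a = comm[i]
                # links to every community, excluding self-weight
                lp = np.bincount(comm, weights=wp[i], minlength=n)
                ln = np.bincount(comm, weights=wn[i], minlength=n)
                lp[a] -= wp[i, i]
                ln[a] -= wn[i, i]
                sp[a] -= kp[i]
                sn[a] -= kn[i]
                gain = np.zeros(n)
                if twp:
                    gain += cp * 2.0 * (lp - kp[i] * sp / twp)
                if twn:
                    gain -= cn * 2.0 * (ln - kn[i] * sn / twn)
                b = int(np.argmax(gain))
                if gain[b] <= gain[a] + self.tol:
                    b = a
                comm[i] = b
                sp[b] += kp[i]
                sn[b] += kn[i]
                if b != a:
                    moved += 1
            moved_any = moved_any or moved > 0
            if moved == 0:
                break
        _, comm = np.unique(comm, return_inverse=True)
        return comm, moved_any

    def _detect(self, w, seed):
        rng = np.random.default_rng(
            _DETERMINISTIC_SEED if seed is None else int(seed)
        )
        wp = np.clip(w, 0.0, None)
        wn = np.clip(-w, 0.0, None)
        twp, twn = wp.sum(), wn.sum()
        cp, cn = self._coeffs(twp, twn, self.objective)
        labels = np.arange(w.shape[0])
        while True:
            comm, moved = self._one_level(wp, wn, cp, cn, twp, twn, rng)
            if not moved:
                break
            labels = comm[labels]
            nc = comm.max() + 1
            onehot = np.zeros((wp.shape[0], nc))
            onehot[np.arange(wp.shape[0]), comm] = 1.0
            wp = onehot.T @ wp @ onehot
            wn = onehot.T @ wn @ onehot
            if nc == 1:
                break
        return labels


@dataclass(frozen=True)
class MethodSpec:
    """Registry entry for one detection method."""

    name: str
    deterministic: bool
    accepts_negative_weights: bool
    factory: Callable[..., BaseCommunityDetector]
    params: dict = field(default_factory=dict)

    def make(self, random_state: Optional[int] = None) -> BaseCommunityDetector:
        return self.factory(random_state=random_state, **self.params)


METHODS: dict[str, MethodSpec] = {
    "NSA": MethodSpec("NSA", True, False, NewmanSpectral),
    "Walktrap": MethodSpec("Walktrap", True, False, Walktrap, {"steps": 4}),
    "FastModularity": MethodSpec("FastModularity", True, False, FastModularity),
    "LouvainGJA": MethodSpec(
        "LouvainGJA", False, True, SignedLouvain, {"objective": "gja"}
    ),
    "LabelPropagation": MethodSpec("LabelPropagation", False, False, LabelPropagation),
    "Infomap": MethodSpec("Infomap", False, False, Infomap),
}

METHOD_NAMES: tuple[str, ...] = tuple(METHODS)


@dataclass(frozen=True)
class DetectionResult:
    """One partition returned by one (seeded) run of a method."""

    method: str
    partition: Partition
    n_communities: int
    run_index: int
    seed: int


def preprocess(matrix: SimilarityMatrix, method: MethodSpec) -> SimilarityMatrix:
    """Apply a method's weight convention: clip negatives unless it is signed."""
    w = _matrix_values(matrix)
    if not method.accepts_negative_weights:
        w = _clip_negative(w)
        if not np.any(w):
            raise DegenerateInputError(
                "matrix is all zero after clipping negatives; every node isolated"
            )
    mtype = matrix.matrix_type if isinstance(matrix, SimilarityMatrix) else (
        MatrixType.COUNT
    )
    return SimilarityMatrix(w, mtype, diagonal_zeroed=True)


def run_method(method: MethodSpec | str, matrix, seed: int = 0, run_index: int = 0
               ) -> DetectionResult:
    """Run one method once on a matrix; nondeterministic methods use ``seed``."""
    spec = METHODS[method] if isinstance(method, str) else method
    est = spec.make(random_state=int(seed))
    est.fit(matrix)
    return DetectionResult(
        method=spec.name,
        partition=Partition(est.labels_),
        n_communities=est.n_communities_,
        run_index=run_index,
        seed=int(seed),
    )


def run_repeated(method: MethodSpec | str, matrix, n_runs: int, seed: int
                 ) -> list[DetectionResult]:
    """``n_runs`` runs with distinct derived seeds (identical for deterministic
    methods)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    spec = METHODS[method] if isinstance(method, str) else method
    results = []
    for r in range(n_runs):
        run_seed = derive_seed(seed, STREAM_DETECT, r)
        results.append(run_method(spec, matrix, seed=run_seed, run_index=r))
    return results
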