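"""Correlation and reflected Euclidean distance benchmarks with planted communities.

The generative model comes from structural equation modeling.  Each node i
belongs to one latent community factor; its loading ``lambda_i`` is drawn
uniformly from the condition's loading range.  With ``Lambda`` the n x K
loading matrix (one nonzero per row), ``Phi`` the K x K factor correlation
matrix (compound symmetric: all off-diagonals equal the condition's overlap)
and ``Theta = diag(1 - lambda_i^2)`` the residual variances, the population
correlation matrix is

    R = Lambda Phi Lambda' + Theta

which has an exact unit diagonal.  Within-community population correlations
are ``lambda_i lambda_j``; between-community correlations are
``overlap * lambda_i lambda_j``, so planted communities are communities in
the strong sense whenever overlap < 1.

From R (plus community-wise mean offsets, the "level differences") we draw
i.i.d. multivariate-normal time points — the matrices reflect only lag-0
relations, with no autocorrelation — and compute two similarity matrices from
the same realization: the Pearson correlation matrix and the reflected
Euclidean distance matrix (each distance subtracted from the maximum pairwise
distance, so the farthest pair maps to 0).  The diagonal of each final matrix
is set to zero, the last construction step before detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._exceptions import GenerationError, InvalidConditionError
from ._seeds import STREAM_CORR, derive_seed
from .conditions import CorrCondition, SizeScheme
from .types import BenchmarkInstance, MatrixType, Partition, SimilarityMatrix, TimeSeriesData

__all__ = [
    "LatentModel",
    "assign_community_sizes",
    "build_population_model",
    "implied_correlation",
    "generate_timeseries",
    "sample_correlation",
    "reflected_euclidean",
    "generate_corr_instance",
]

_PSD_TOL = -1e-8


@dataclass(frozen=True)
class LatentModel:
    """Population latent-community model: loadings, factor correlations,
    residual variances, community mean offsets and the planted assignment."""

    loadings: np.ndarray  # per-node loading on its own community factor
    factor_corr: np.ndarray  # K x K, compound symmetric
    residual_var: np.ndarray  # per-node, 1 - loading^2
    community_means: np.ndarray  # per-community mean offset
    assignment: Partition

    @property
    def n_nodes(self) -> int:
        return self.assignment.n_nodes

    @property
    def n_communities(self) -> int:
        return self.factor_corr.shape[0]


def assign_community_sizes(
    n_nodes: int, n_communities: int, scheme: SizeScheme | str
) -> list[int]:
    """Split ``n_nodes`` into ``n_communities`` sizes under a size scheme.

    ``equal`` gives sizes differing by at most one.  The unequal schemes mix
    "large" and "small" communities at a 3:1 size ratio, with the large:small
    count composition 50/50 (as many large as small), 75/25 (more large) or
    25/75 (more small); the last community absorbs the rounding remainder.
    """
    scheme = SizeScheme(scheme)
    if n_communities < 1 or n_communities > n_nodes:
        raise InvalidConditionError(
            f"cannot split {n_nodes} nodes into {n_communities} communities"
        )
    if scheme is SizeScheme.EQUAL or n_communities == 1:
        base, rem = divmod(n_nodes, n_communities)
        return [base + 1 if i < rem else base for i in range(n_communities)]

    prop_large = {
        SizeScheme.AS_MANY_LARGE_AS_SMALL: 0.5,
        SizeScheme.MORE_LARGE_THAN_SMALL: 0.75,
        SizeScheme.MORE_SMALL_THAN_LARGE: 0.25,
    }[scheme]
    n_large = min(max(int(round(prop_large * n_communities)), 1), n_communities - 1)
    n_small = n_communities - n_large
    # large = 3 * small; scale the small size so the composition sums to n
    small_f = n_nodes / (3 * n_large + n_small)
    small = max(int(round(small_f)), 1)
    large = max(int(round(3 * small_f)), 1)
    sizes = [large] * n_large + [small] * n_small
    sizes[-1] += n_nodes - sum(sizes)
    if sizes[-1] < 1:
        raise InvalidConditionError(
            f"size scheme {scheme.value} infeasible for "
            f"({n_nodes} nodes, {n_communities} communities)"
        )
    return sizes


def build_population_model(condition: CorrCondition, seed: int) -> LatentModel:
    """Draw a population model for one replicate of a condition.

    Loadings are uniform on the condition's loading range; the factor
    correlation matrix has all off-diagonals equal to the overlap; community
    mean offsets are (k-1) * level_diff; residual variances complete every
    node variance to exactly 1.
    """
    rng = np.random.default_rng(seed)
    sizes = assign_community_sizes(
        condition.n_nodes, condition.n_communities, condition.size_scheme
    )
    assignment = Partition.from_sizes(sizes)
    lo, hi = condition.loading_range
    loadings = rng.uniform(lo, hi, size=condition.n_nodes)
    k = condition.n_communities
    factor_corr = np.full((k, k), condition.overlap)
    np.fill_diagonal(factor_corr, 1.0)
    residual_var = 1.0 - loadings**2
    means = np.arange(k) * condition.level_diff
    model = LatentModel(loadings, factor_corr, residual_var, means, assignment)
    # PSD check on the true (unit-diagonal) population matrix
    r_full = _implied_full(model)
    if np.linalg.eigvalsh(r_full).min() < _PSD_TOL:
        raise GenerationError(
            f"condition {condition.id}: implied correlation matrix is not PSD"
        )
    return model


def _implied_full(model: LatentModel) -> np.ndarray:
    lam = np.zeros((model.n_nodes, model.n_communities))
    lam[np.arange(model.n_nodes), model.assignment.labels - 1] = model.loadings
    r = lam @ model.factor_corr @ lam.T
    np.fill_diagonal(r, 1.0)
    return r


def implied_correlation(model: LatentModel) -> SimilarityMatrix:
    """Population correlation matrix Lambda Phi Lambda' + Theta (unit diagonal).

    This is the object the time series are sampled from; its diagonal is not
    yet zeroed.
    """
    return SimilarityMatrix(
        _implied_full(model), MatrixType.CORRELATION, diagonal_zeroed=False
    )


def generate_timeseries(model: LatentModel, t_obs: int, seed: int) -> TimeSeriesData:
    """Sample ``t_obs`` i.i.d. multivariate-normal time points from the model.

    Rows are nodes, columns time points.  Node means are their community's
    offset; covariance is the implied population correlation.  No temporal
    structure is induced (lag-0 relations only).
    """
    if t_obs <= 0:
        raise ValueError("t_obs must be positive")
    rng = np.random.default_rng(seed)
    r = _implied_full(model)
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(r)
        if w.min() < _PSD_TOL:
            raise GenerationError("implied covariance is not positive semi-definite")
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    values = chol @ rng.standard_normal((model.n_nodes, t_obs))
    values += model.community_means[model.assignment.labels - 1][:, None]
    return TimeSeriesData(values=values, assignment=model.assignment, seed=int(seed))


def sample_correlation(ts: TimeSeriesData) -> SimilarityMatrix:
    """Pearson correlation across time for every node pair, diagonal zeroed."""
    if ts.t_obs < 3:
        raise ValueError("need at least 3 time points for a sample correlation")
    sd = ts.values.std(axis=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise GenerationError(f"node {int(zero[0])} has zero variance across time")
    corr = np.corrcoef(ts.values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(corr, MatrixType.CORRELATION, diagonal_zeroed=True)


def reflected_euclidean(ts: TimeSeriesData) -> SimilarityMatrix:
    """Reflected Euclidean distances: |d_ij - max d|, diagonal zeroed.

    The farthest pair maps to exactly 0 (no similarity) and identical series
    map to the maximum distance; the distance ordering is reversed.
    """
    if ts.n_nodes < 2:
        raise ValueError("need at least two nodes")
    d = pdist(ts.values, metric="euclidean")
    refl = np.abs(d - d.max())
    return SimilarityMatrix(
        squareform(refl), MatrixType.REFLECTED_EUCD, diagonal_zeroed=True
    )


def generate_corr_instance(
    condition: CorrCondition, replicate: int, seed: int
) -> tuple[BenchmarkInstance, BenchmarkInstance]:
    """One replicate: (correlation instance, reflected-EucD instance).

    Both matrices come from the SAME time-series realization and share one
    planted partition.  ``seed`` is the study master seed; the instance seed
    is derived from (master, condition, replicate) and recorded.
    """
    inst_seed = derive_seed(seed, STREAM_CORR, condition.id, replicate)
    # distinct sub-streams so loadings and time-series noise are independent
    model = build_population_model(condition, derive_seed(inst_seed, 1))
    ts = generate_timeseries(model, condition.t_obs, derive_seed(inst_seed, 2))
    corr = sample_correlation(ts)
    eucd = reflected_euclidean(ts)
    mk = lambda m, t: BenchmarkInstance(  # noqa: E731
        matrix=m,
        truth=model.assignment,
        condition_id=condition.id,
        matrix_type=t,
        replicate=replicate,
        seed=inst_seed,
    )
    return mk(corr, MatrixType.CORRELATION), mk(eucd, MatrixType.REFLECTED_EUCD)
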