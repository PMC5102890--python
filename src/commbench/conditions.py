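"""Simulation condition registries.

Two families of Monte Carlo conditions are benchmarked:

* ``LfrCondition`` — sparse count (0/1 adjacency) graphs in the
  Lancichinetti–Fortunato–Radicchi style, parameterized by graph size,
  average/maximum degree, the mixing parameter (proportion of out-of-community
  edges) and the community-size power-law exponent.

* ``CorrCondition`` — dense similarity matrices (Pearson correlation and
  reflected Euclidean distance) derived from multivariate time series with a
  latent-community factor structure, parameterized by graph size, the
  within-community loading range, the community-size scheme, the number of
  communities, the between-community factor correlation ("overlap") and a
  community-wise mean offset ("level difference").

The registries below enumerate the 28 count-matrix conditions and the 39
similarity-matrix conditions of the published study design, one hundred
replicates of which constitute the full Monte Carlo sweep.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from ._exceptions import InvalidConditionError

__all__ = [
    "SizeScheme",
    "CorrCondition",
    "LfrCondition",
    "ConditionRegistry",
    "load_registry",
]


class SizeScheme(str, enum.Enum):
    """How node counts are split across planted communities."""

    EQUAL = "equal"
    AS_MANY_LARGE_AS_SMALL = "as_many_large_as_small"
    MORE_LARGE_THAN_SMALL = "more_large_than_small"
    MORE_SMALL_THAN_LARGE = "more_small_than_large"


@dataclass(frozen=True)
class CorrCondition:
    """One similarity-matrix simulation condition.

    ``t_obs`` is the number of time points sampled per node: 502 for graphs of
    up to 500 nodes and 1002 for 1000-node graphs, so that observations always
    outnumber nodes (as in a typical resting-state fMRI acquisition).
    """

    id: int
    n_nodes: int
    loading_range: tuple[float, float]
    size_scheme: SizeScheme
    n_communities: int
    overlap: float
    level_diff: float
    t_obs: int = field(default=0)

    def __post_init__(self) -> None:
        if self.t_obs == 0:
            object.__setattr__(self, "t_obs", 1002 if self.n_nodes >= 1000 else 502)
        lo, hi = self.loading_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidConditionError(
                f"condition {self.id}: loading range ({lo}, {hi}) must satisfy "
                "0 <= low <= high <= 1"
            )
        if self.n_communities < 1 or self.n_communities > self.n_nodes:
            raise InvalidConditionError(
                f"condition {self.id}: need 1 <= n_communities <= n_nodes"
            )
        if not (0.0 <= self.overlap < 1.0):
            raise InvalidConditionError(
                f"condition {self.id}: overlap {self.overlap} outside [0, 1)"
            )
        if self.level_diff < 0:
            raise InvalidConditionError(f"condition {self.id}: negative level_diff")
        if self.t_obs <= self.n_nodes:
            raise InvalidConditionError(
                f"condition {self.id}: t_obs must exceed n_nodes"
            )


@dataclass(frozen=True)
class LfrCondition:
    """One sparse count-matrix simulation condition.

    ``prop_out`` is the mixing parameter mu: the expected fraction of each
    node's edges that attach outside its community.  ``size_hetero`` is the
    community-size power-law exponent (1 = low heterogeneity, 2 = high).
    """

    id: int
    n_nodes: int
    avg_degree: float
    max_degree: int
    prop_out: float
    size_hetero: int

    def __post_init__(self) -> None:
        if not (0 < self.avg_degree <= self.max_degree < self.n_nodes):
            raise InvalidConditionError(
                f"condition {self.id}: need 0 < avg_degree <= max_degree < n_nodes"
            )
        if not (0.0 <= self.prop_out < 1.0):
            raise InvalidConditionError(
                f"condition {self.id}: prop_out {self.prop_out} outside [0, 1)"
            )
        if self.size_hetero not in (1, 2):
            raise InvalidConditionError(
                f"condition {self.id}: size_hetero must be 1 or 2"
            )


def _lfr(id_, n, avg, mx, mu, het):
    return LfrCondition(id_, n, avg, mx, mu, het)


#: 28 sparse count conditions: (id, nodes, avg degree, max degree, prop out, hetero)
LFR_CONDITIONS: tuple[LfrCondition, ...] = tuple(
    _lfr(*row)
    for row in [
        (1, 25, 2, 4, 0.1, 1),
        (2, 25, 3, 4, 0.1, 1),
        (3, 25, 2, 4, 0.1, 2),
        (4, 25, 3, 4, 0.1, 2),
        (5, 75, 4, 15, 0.1, 1),
        (6, 75, 4, 15, 0.1, 2),
        (7, 75, 6, 15, 0.1, 1),
        (8, 75, 6, 15, 0.1, 2),
        (9, 75, 10, 15, 0.1, 1),
        (10, 75, 10, 15, 0.1, 2),
        (11, 500, 8, 30, 0.1, 1),
        (12, 500, 8, 30, 0.1, 2),
        (13, 500, 12, 30, 0.1, 1),
        (14, 500, 12, 30, 0.1, 2),
        (15, 500, 15, 30, 0.1, 1),
        (16, 500, 15, 30, 0.1, 2),
        (17, 1000, 15, 50, 0.1, 1),
        (18, 1000, 15, 50, 0.1, 2),
        (19, 1000, 15, 50, 0.3, 1),
        (20, 1000, 15, 50, 0.3, 2),
        (21, 1000, 20, 50, 0.1, 1),
        (22, 1000, 20, 50, 0.1, 2),
        (23, 1000, 20, 50, 0.3, 1),
        (24, 1000, 20, 50, 0.3, 2),
        (25, 1000, 25, 50, 0.1, 1),
        (26, 1000, 25, 50, 0.1, 2),
        (27, 1000, 25, 50, 0.3, 1),
        (28, 1000, 25, 50, 0.3, 2),
    ]
)

_EQ = SizeScheme.EQUAL
_AM = SizeScheme.AS_MANY_LARGE_AS_SMALL
_ML = SizeScheme.MORE_LARGE_THAN_SMALL
_MS = SizeScheme.MORE_SMALL_THAN_LARGE


def _corr(id_, n, lo, hi, scheme, k, overlap, level):
    return CorrCondition(id_, n, (lo, hi), scheme, k, overlap, level)


#: 39 similarity-matrix conditions:
#: (id, nodes, loading low, loading high, scheme, communities, overlap, level diff)
CORR_CONDITIONS: tuple[CorrCondition, ...] = tuple(
    _corr(*row)
    for row in [
        (1, 25, 0.25, 0.95, _EQ, 2, 0.1, 0),
        (2, 25, 0.25, 0.95, _EQ, 2, 0.1, 1),
        (3, 25, 0.5, 0.5, _EQ, 2, 0.1, 0),
        (4, 25, 0.25, 0.95, _EQ, 4, 0.1, 0),
        (5, 25, 0.25, 0.95, _AM, 4, 0.1, 0),
        (6, 25, 0.25, 0.95, _EQ, 5, 0.1, 0),
        (7, 75, 0.25, 0.95, _EQ, 2, 0.1, 0),
        (8, 75, 0.25, 0.95, _EQ, 4, 0.1, 0),
        (9, 75, 0.25, 0.95, _EQ, 4, 0.1, 1),
        (10, 75, 0.25, 0.95, _AM, 4, 0.1, 0),
        (11, 75, 0.5, 0.5, _EQ, 4, 0.1, 0),
        (12, 75, 0.25, 0.95, _EQ, 8, 0.1, 0),
        (13, 500, 0.25, 0.95, _EQ, 2, 0.1, 0),
        (14, 500, 0.25, 0.95, _EQ, 5, 0.1, 0),
        (15, 500, 0.25, 0.95, _EQ, 10, 0.1, 0),
        (16, 500, 0.25, 0.95, _EQ, 10, 0.1, 1),
        (17, 500, 0.25, 0.95, _AM, 10, 0.1, 0),
        (18, 500, 0.5, 0.5, _EQ, 10, 0.1, 0),
        (19, 500, 0.25, 0.95, _EQ, 20, 0.1, 0),
        (20, 1000, 0.25, 0.95, _EQ, 1, 0.1, 0),
        (21, 1000, 0.25, 0.95, _EQ, 2, 0.1, 0),
        (22, 1000, 0.25, 0.95, _EQ, 4, 0.1, 0),
        (23, 1000, 0.01, 0.01, _EQ, 10, 0.1, 0),
        (24, 1000, 0.1, 0.1, _EQ, 10, 0.1, 1),
        (25, 1000, 0.1, 0.95, _EQ, 10, 0.1, 0),
        (26, 1000, 0.25, 0.25, _EQ, 10, 0.1, 0),
        (27, 1000, 0.25, 0.95, _EQ, 10, 0.1, 0),
        (28, 1000, 0.25, 0.95, _EQ, 10, 0.25, 0),
        (29, 1000, 0.25, 0.95, _EQ, 10, 0.75, 0),
        (30, 1000, 0.25, 0.95, _EQ, 10, 0.1, 1),
        (31, 1000, 0.25, 0.95, _EQ, 10, 0.1, 5),
        (32, 1000, 0.25, 0.95, _ML, 10, 0.1, 0),
        (33, 1000, 0.25, 0.95, _AM, 10, 0.1, 0),
        (34, 1000, 0.25, 0.95, _MS, 10, 0.1, 0),
        (35, 1000, 0.5, 0.95, _EQ, 10, 0.1, 0),
        (36, 1000, 0.75, 0.75, _EQ, 10, 0.1, 0),
        (37, 1000, 0.75, 0.95, _EQ, 10, 0.1, 0),
        (38, 1000, 0.95, 0.95, _EQ, 10, 0.1, 0),
        (39, 1000, 0.25, 0.95, _EQ, 20, 0.1, 0),
    ]
)


@dataclass(frozen=True)
class ConditionRegistry:
    """The full study design: 28 count and 39 similarity conditions."""

    lfr: tuple[LfrCondition, ...]
    corr: tuple[CorrCondition, ...]

    def lfr_by_id(self, id_: int) -> LfrCondition:
        for c in self.lfr:
            if c.id == id_:
                return c
        raise KeyError(f"no LFR condition with id {id_}")

    def corr_by_id(self, id_: int) -> CorrCondition:
        for c in self.corr:
            if c.id == id_:
                return c
        raise KeyError(f"no correlation condition with id {id_}")


def load_registry() -> ConditionRegistry:
    """Return the registry of all 28 + 39 study conditions."""
    return ConditionRegistry(lfr=LFR_CONDITIONS, corr=CORR_CONDITIONS)
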