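"""Sparse count benchmark graphs in the Lancichinetti–Fortunato–Radicchi style.

These emulate structural (streamline-count-like) connectivity: simple,
undirected 0/1 graphs whose degrees follow a truncated power law with exponent
2 and whose community sizes follow a power law with exponent 1 or 2.  Each
node's edges are split into internal and external stubs according to the
mixing parameter mu ("prop out"); stubs are then matched by a configuration
model with rewiring to forbid self-loops, multi-edges and (for external
stubs) within-community edges.  Because community sizes are bounded below by
max_degree + 1, every node can host its internal degree, and for mu < 0.5
each node's expected internal degree exceeds its external degree — the
planted partition is a community structure in the strong sense.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.optimize import brentq

from ._exceptions import GenerationError, InvalidConditionError
from ._seeds import STREAM_LFR, derive_seed
from .conditions import LfrCondition
from .types import BenchmarkInstance, MatrixType, Partition, SimilarityMatrix

__all__ = [
    "sample_degree_sequence",
    "sample_community_sizes_lfr",
    "wire_lfr_graph",
    "generate_lfr_instance",
    "community_size_bounds",
]

_DEGREE_EXPONENT = 2.0


def _truncated_pareto_mean(a: float, b: float) -> float:
    """Mean of the continuous power law p(x) ~ x^-2 truncated to [a, b]."""
    if a >= b:
        return a
    return float(np.log(b / a) / (1.0 / a - 1.0 / b))


def _solve_lower_cutoff(avg_degree: float, max_degree: int) -> float:
    """Lower cutoff of the exponent-2 power law whose truncated mean is avg_degree."""
    lo, hi = 1e-6, float(max_degree) - 1e-9
    f = lambda a: _truncated_pareto_mean(a, max_degree) - avg_degree  # noqa: E731
    if f(hi) < 0 or f(lo) > 0:
        raise InvalidConditionError(
            f"no power-law lower cutoff gives mean degree {avg_degree} "
            f"with max degree {max_degree}"
        )
    return float(brentq(f, lo, hi, xtol=1e-12))


def sample_degree_sequence(condition: LfrCondition, seed: int) -> np.ndarray:
    """Degrees from a truncated exponent-2 power law with even total.

    The lower cutoff is solved numerically so the continuous distribution's
    mean equals the condition's average degree; draws are rounded to integers
    in [1, max_degree].
    """
    rng = np.random.default_rng(seed)
    a = _solve_lower_cutoff(condition.avg_degree, condition.max_degree)
    b = float(condition.max_degree)
    # inverse CDF of x^-2 on [a, b]
    u = rng.uniform(size=condition.n_nodes)
    norm = 1.0 / a - 1.0 / b
    x = 1.0 / (1.0 / a - u * norm)
    degrees = np.clip(np.rint(x).astype(np.int64), 1, condition.max_degree)
    if degrees.sum() % 2 == 1:  # force even stub total
        i = int(np.argmax(degrees < condition.max_degree))
        degrees[i] += 1
    return degrees


def community_size_bounds(condition: LfrCondition) -> tuple[int, int]:
    """Feasible [min, max] community sizes for a condition.

    The minimum is max_degree + 1 so any node can place its internal degree;
    the maximum starts at ceil(0.2 * n) and is minimally widened until some
    number of communities m satisfies m*min <= n <= m*max.
    """
    n = condition.n_nodes
    smin = condition.max_degree + 1
    if smin > n:
        raise InvalidConditionError(
            f"condition {condition.id}: minimum community size {smin} exceeds "
            f"graph size {n}"
        )
    smax = max(int(np.ceil(0.2 * n)), smin)
    while not any(
        m * smin <= n <= m * smax for m in range(1, n // smin + 1)
    ):
        smax += 1
    return smin, smax


def sample_community_sizes_lfr(condition: LfrCondition, seed: int) -> list[int]:
    """Community sizes from a power law with exponent ``size_hetero``.

    Sizes are drawn sequentially from p(s) ~ s^-tau on [smin, smax] until the
    running total reaches n; the final draw is adjusted (and, if needed, the
    excess redistributed) so sizes sum exactly to n within the bounds.
    """
    rng = np.random.default_rng(seed)
    smin, smax = community_size_bounds(condition)
    n = condition.n_nodes
    tau = float(condition.size_hetero)
    support = np.arange(smin, smax + 1, dtype=float)
    probs = support**-tau
    probs /= probs.sum()
    for _ in range(10_000):
        sizes: list[int] = []
        total = 0
        while total < n:
            s = int(rng.choice(support, p=probs))
            sizes.append(s)
            total += s
        excess = total - n
        if excess == 0:
            return sizes
        if sizes[-1] - excess >= smin:
            sizes[-1] -= excess
            return sizes
        # push the shortfall onto earlier communities with headroom
        sizes.pop()
        deficit = n - sum(sizes)
        if sizes and 0 <= deficit:
            for i in range(len(sizes)):
                room = smax - sizes[i]
                add = min(room, deficit)
                sizes[i] += add
                deficit -= add
                if deficit == 0:
                    return sizes
    raise GenerationError(
        f"condition {condition.id}: could not draw community sizes summing to {n}"
    )


def _erdos_gallai(deg: np.ndarray) -> bool:
    """True if the even-sum degree sequence is realizable as a simple graph."""
    d = np.sort(np.asarray(deg, dtype=np.int64))[::-1]
    if d.sum() % 2:
        return False
    n = d.size
    cum = np.cumsum(d)
    for k in range(1, n + 1):
        rhs = k * (k - 1) + np.minimum(d[k:], k).sum()
        if cum[k - 1] > rhs:
            return False
    return True


def _repair_internal(
    d_int: np.ndarray, idx: np.ndarray, dropped: np.ndarray | None = None
) -> None:
    """Shift internal stubs to external until the community sequence is graphical.

    Decrements the two largest internal degrees (preserving parity); the freed
    stubs become external, or are dropped outright when ``dropped`` is given
    (the mu = 0 limit, where no external edges may exist).  In-place.
    """
    for _ in range(int(d_int[idx].sum()) + 1):
        if _erdos_gallai(d_int[idx]):
            return
        order = idx[np.argsort(d_int[idx])[::-1]]
        if d_int[order[1]] > 0:
            freed = [order[0], order[1]]
            d_int[order[0]] -= 1
            d_int[order[1]] -= 1
        else:  # lone positive degree: both stubs must leave the same node
            freed = [order[0], order[0]]
            d_int[order[0]] -= 2
        if dropped is not None:
            for i in freed:
                dropped[i] += 1
    raise GenerationError("could not repair internal degree sequence")


def _match_stubs(
    stubs: np.ndarray,
    rng: np.random.Generator,
    community: np.ndarray | None = None,
    existing: set[tuple[int, int]] | None = None,
    max_rounds: int = 200,
    strict: bool = True,
) -> list[tuple[int, int]]:
    """Configuration-model pairing with local rewiring.

    Pairs the stub list (node indices, one entry per half-edge), rejecting
    self-loops, duplicate edges and — when ``community`` is given — pairs
    inside the same community.  Bad pairs are repaired by swapping endpoints
    with randomly chosen good pairs; a bounded number of rounds is attempted.
    """
    existing = set(existing or ())

    def bad(u: int, v: int, edge_set: set) -> bool:
        if u == v:
            return True
        e = (u, v) if u < v else (v, u)
        if e in edge_set or e in existing:
            return True
        return community is not None and community[u] == community[v]

    stubs = np.asarray(stubs)
    for _ in range(max_rounds):
        perm = rng.permutation(stubs)
        pairs = [(int(perm[i]), int(perm[i + 1])) for i in range(0, len(perm) - 1, 2)]
        edge_set: set[tuple[int, int]] = set()
        bad_idx = []
        for i, (u, v) in enumerate(pairs):
            if bad(u, v, edge_set):
                bad_idx.append(i)
            else:
                edge_set.add((u, v) if u < v else (v, u))
        if not bad_idx:
            return pairs
        # local rewiring: swap each bad pair with random partners
        for _ in range(50 * len(pairs)):
            if not bad_idx:
                break
            i = bad_idx[-1]
            j = int(rng.integers(len(pairs)))
            if i == j:
                continue
            u1, v1 = pairs[i]
            u2, v2 = pairs[j]
            e2 = (u2, v2) if u2 < v2 else (v2, u2)
            ok2 = e2 in edge_set
            # try the swap (u1, v2), (u2, v1)
            cand1, cand2 = (u1, v2), (u2, v1)
            if ok2:
                edge_set.discard(e2)
            c1_bad = bad(*cand1, edge_set)
            t1 = (min(cand1), max(cand1))
            if not c1_bad:
                edge_set.add(t1)
            c2_bad = bad(*cand2, edge_set)
            if c1_bad or c2_bad:
                # revert
                if not c1_bad:
                    edge_set.discard(t1)
                if ok2:
                    edge_set.add(e2)
                continue
            edge_set.add((min(cand2), max(cand2)))
            pairs[i], pairs[j] = cand1, cand2
            bad_idx.pop()
            if j in bad_idx:
                bad_idx.remove(j)
        if not bad_idx:
            return pairs
    if not strict:  # drop unresolvable pairs (bounded degree shortfall)
        keep = set(range(len(pairs))) - set(bad_idx)
        return [pairs[i] for i in sorted(keep)]
    raise GenerationError("stub matching failed: rewiring budget exhausted")


def wire_lfr_graph(
    degrees: np.ndarray,
    sizes: list[int],
    prop_out: float,
    seed: int,
    condition_id: int = 0,
    replicate: int = 0,
) -> BenchmarkInstance:
    """Wire a simple 0/1 graph from degrees, community sizes and mixing mu.

    Each node's external degree is mu * k in expectation (floor plus a
    Bernoulli on the fractional part, so realized mixing tracks mu at every
    degree); internal stub totals are made even per community by adjusting the
    community's last node.  Internal stubs are matched within communities and
    external stubs across communities, both by configuration-model pairing
    with rewiring.
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    n = degrees.size
    if degrees.sum() % 2:
        raise InvalidConditionError("degree sum must be even")
    if sum(sizes) != n:
        raise InvalidConditionError("community sizes must sum to the node count")
    rng = np.random.default_rng(seed)
    truth = Partition.from_sizes(sizes)

    # Infeasible stub configurations (possible at very small degree/graph
    # sizes) are retried with a fresh internal/external split; a final relaxed
    # attempt drops unresolvable external stub pairs.
    last_err: GenerationError | None = None
    for attempt in range(20):
        try:
            adj = _wire_once(degrees, truth, prop_out, rng, strict=attempt < 19)
            break
        except GenerationError as err:
            last_err = err
    else:
        raise GenerationError(
            f"graph wiring failed after retries: {last_err}"
        )

    matrix = SimilarityMatrix(adj, MatrixType.COUNT, diagonal_zeroed=True)
    return BenchmarkInstance(
        matrix=matrix,
        truth=truth,
        condition_id=condition_id,
        matrix_type=MatrixType.COUNT,
        replicate=replicate,
        seed=int(seed),
    )


def _wire_once(
    degrees: np.ndarray,
    truth: Partition,
    prop_out: float,
    rng: np.random.Generator,
    strict: bool,
) -> np.ndarray:
    n = degrees.size
    comm = truth.labels

    ext_f = prop_out * degrees
    d_ext = np.floor(ext_f).astype(np.int64)
    d_ext += (rng.uniform(size=n) < (ext_f - d_ext)).astype(np.int64)
    d_ext = np.minimum(d_ext, degrees)
    d_int = degrees - d_ext
    # stubs dropped outright (parity repair when no external stub can absorb
    # them, e.g. at mu = 0); these reduce the realized degree by one
    dropped = np.zeros(n, dtype=np.int64)

    # internal-degree feasibility, per-community parity (fixed on the last
    # capable node) and simple-graph realizability
    for c in range(1, truth.n_communities + 1):
        idx = np.flatnonzero(comm == c)
        cap = idx.size - 1
        over = d_int[idx] > cap
        d_int[idx[over]] = cap
        if d_int[idx].sum() % 2:
            last = idx[-1]
            if d_int[last] < min(cap, degrees[last]) and d_ext[last] > 0:
                d_int[last] += 1  # absorb one of the node's external stubs
            else:
                cand = idx[d_int[idx] > 0][-1]
                d_int[cand] -= 1
                if prop_out == 0.0:
                    dropped[cand] += 1
        _repair_internal(d_int, idx, dropped if prop_out == 0.0 else None)
    d_ext = degrees - d_int - dropped

    # external matching feasibility: no community may hold more than half of
    # all external stubs; shift stub pairs back internal where there is room
    for _ in range(int(d_ext.sum()) + 1):
        if d_ext.sum() == 0:
            break
        per_comm = np.bincount(comm, weights=d_ext)
        heavy = int(np.argmax(per_comm))
        if 2 * per_comm[heavy] <= d_ext.sum():
            break
        idx = np.flatnonzero(comm == heavy)
        cap = idx.size - 1
        applied = 0
        for i in np.tile(idx, 2):  # allow taking two stubs from one node
            if applied == 2:
                break
            if d_ext[i] > 0 and d_int[i] < cap:
                d_int[i] += 1
                d_ext[i] -= 1
                applied += 1
        if applied != 2:
            raise GenerationError("external stub imbalance cannot be repaired")
        if not _erdos_gallai(d_int[idx]):
            _repair_internal(d_int, idx)
            d_ext = degrees - d_int - dropped

    edges: list[tuple[int, int]] = []
    for c in range(1, truth.n_communities + 1):
        idx = np.flatnonzero(comm == c)
        stubs = np.repeat(idx, d_int[idx])
        if stubs.size:
            edges.extend(_match_stubs(stubs, rng))
    if d_ext.sum():
        stubs = np.repeat(np.arange(n), d_ext)
        existing = {(min(u, v), max(u, v)) for u, v in edges}
        edges.extend(
            _match_stubs(stubs, rng, community=comm, existing=existing, strict=strict)
        )

    adj = np.zeros((n, n))
    for u, v in edges:
        adj[u, v] = 1.0
        adj[v, u] = 1.0
    return adj


def generate_lfr_instance(
    condition: LfrCondition, replicate: int, seed: int
) -> BenchmarkInstance:
    """One sparse count benchmark replicate for a registry condition.

    ``seed`` is the study master seed; the instance seed is derived from
    (master, condition, replicate) and recorded on the instance.
    """
    inst_seed = derive_seed(seed, STREAM_LFR, condition.id, replicate)
    # distinct sub-streams so degrees, sizes and wiring draws are independent
    degrees = sample_degree_sequence(condition, derive_seed(inst_seed, 1))
    sizes = sample_community_sizes_lfr(condition, derive_seed(inst_seed, 2))
    inst = wire_lfr_graph(
        degrees,
        sizes,
        condition.prop_out,
        derive_seed(inst_seed, 3),
        condition_id=condition.id,
        replicate=replicate,
    )
    return replace(inst, seed=inst_seed)
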