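"""Independent brute-force oracles used to pin down expected metric values.

These deliberately avoid the package's vectorized code paths: modularity as a
literal double sum, the Rand index by enumerating node pairs, and optimal
partitions by exhaustive search over all set partitions of small node sets.
"""

from itertools import combinations

import numpy as np


def brute_modularity(w: np.ndarray, labels: np.ndarray) -> float:
    """Literal double-sum weighted modularity over ordered pairs."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    two_w = w.sum()
    strength = w.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - strength[i] * strength[j] / two_w
    return q / two_w


def brute_pair_counts(truth: np.ndarray, rec: np.ndarray):
    """(a, b, c, d) by enumerating every unordered node pair."""
    a = b = c = d = 0
    for i, j in combinations(range(len(truth)), 2):
        st, sr = truth[i] == truth[j], rec[i] == rec[j]
        if st and sr:
            a += 1
        elif st:
            b += 1
        elif sr:
            c += 1
        else:
            d += 1
    return a, b, c, d


def brute_ari(truth: np.ndarray, rec: np.ndarray) -> float:
    a, b, c, d = brute_pair_counts(truth, rec)
    n2 = a + b + c + d
    cross = (a + b) * (a + c) + (c + d) * (b + d)
    num = n2 * (a + d) - cross
    den = n2 * n2 - cross
    return 1.0 if den == 0 and num == 0 else num / den


def set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""

    def rec(i, labels, k):
        if i == n:
            yield np.array(labels)
            return
        for lab in range(k + 1):
            labels.append(lab)
            yield from rec(i + 1, labels, max(k, lab + 1))
            labels.pop()

    yield from rec(0, [], 0)


def brute_best_modularity_partition(w: np.ndarray):
    """Exhaustively modularity-optimal labeling (n <= ~10)."""
    best, best_q = None, -np.inf
    for labels in set_partitions(w.shape[0]):
        q = brute_modularity(w, labels)
        if q > best_q + 1e-12:
            best, best_q = labels, q
    return best, best_q


def brute_signed_modularity(w: np.ndarray, labels: np.ndarray, objective="gja") -> float:
    """Signed modularity by explicit positive/negative double sums."""
    wp = np.clip(w, 0, None)
    wn = np.clip(-w, 0, None)
    twp, twn = wp.sum(), wn.sum()
    if objective == "gja":
        cp = cn = 1.0 / (twp + twn)
    elif objective == "sta":
        cp, cn = (1.0 / twp if twp else 0.0), 1.0 / (twp + twn)
    else:
        raise ValueError(objective)
    q = 0.0
    n = w.shape[0]
    kp, kn = wp.sum(axis=1), wn.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                if twp:
                    q += cp * (wp[i, j] - kp[i] * kp[j] / twp)
                if twn:
                    q -= cn * (wn[i, j] - kn[i] * kn[j] / twn)
    return q


def brute_best_signed_partition(w: np.ndarray, objective="gja"):
    best, best_q = None, -np.inf
    for labels in set_partitions(w.shape[0]):
        q = brute_signed_modularity(w, labels, objective)
        if q > best_q + 1e-12:
            best, best_q = labels, q
    return best, best_q
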