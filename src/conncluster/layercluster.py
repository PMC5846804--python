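"""Per-layer k-medoids (PAM) partitions of nodal distance matrices.

Each distance layer is partitioned into k groups by Partitioning Around
Medoids: a deterministic greedy BUILD initialization plus random restarts,
each followed by steepest-descent SWAP until no cost-decreasing swap exists.
The inner loops are numba-compiled; swap deltas use the nearest/second-
nearest decomposition so a full swap scan is O(m^2 + m k) instead of
O(m^2 k^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from conncluster.errors import ContractError
from conncluster.distance import NodalDistanceStack


@dataclass
class LayerPartition:
    """One k-medoids assignment of m subjects for one (node, k) pair.

    ``labels`` are 1-based cluster IDs; ``cost`` is the sum of distances of
    every subject to its medoid.
    """

    node_index: int
    k_requested: int
    labels: np.ndarray
    medoid_indices: np.ndarray
    cost: float

    @property
    def k_actual(self) -> int:
        return len(np.unique(self.labels))

    @property
    def m(self) -> int:
        return len(self.labels)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


@njit(cache=True)
def _build_init(D, k):
    """Greedy BUILD: start from the 1-medoid optimum, add the point giving
    the largest cost reduction at each step."""
    m = D.shape[0]
    medoids = np.empty(k, dtype=np.int64)
    rowsums = np.zeros(m)
    for i in range(m):
        for j in range(m):
            rowsums[i] += D[i, j]
    first = 0
    for i in range(1, m):
        if rowsums[i] < rowsums[first]:
            first = i
    medoids[0] = first
    d_near = D[:, first].copy()
    chosen = np.zeros(m, dtype=np.bool_)
    chosen[first] = True
    for t in range(1, k):
        best_j = -1
        best_gain = -1.0
        for j in range(m):
            if chosen[j]:
                continue
            gain = 0.0
            for o in range(m):
                red = d_near[o] - D[o, j]
                if red > 0.0:
                    gain += red
            if gain > best_gain:
                best_gain = gain
                best_j = j
        medoids[t] = best_j
        chosen[best_j] = True
        for o in range(m):
            if D[o, best_j] < d_near[o]:
                d_near[o] = D[o, best_j]
    return medoids


@njit(cache=True)
def _swap_descent(D, medoids):
    """Steepest-descent SWAP; mutates ``medoids``; returns the final cost."""
    m = D.shape[0]
    k = medoids.shape[0]
    is_medoid = np.zeros(m, dtype=np.bool_)
    for t in range(k):
        is_medoid[medoids[t]] = True
    n1 = np.empty(m, dtype=np.int64)  # index into medoids of the nearest
    d1 = np.empty(m)
    d2 = np.empty(m)
    max_iter = 100 * k
    for _ in range(max_iter):
        # nearest and second-nearest medoid distances per point
        for o in range(m):
            b1 = np.inf
            b2 = np.inf
            bi = 0
            for t in range(k):
                d = D[o, medoids[t]]
                if d < b1:
                    b2 = b1
                    b1 = d
                    bi = t
                elif d < b2:
                    b2 = d
            n1[o] = bi
            d1[o] = b1
            d2[o] = b2
        best_delta = -1e-12
        best_t = -1
        best_j = -1
        acc = np.empty(k)
        for j in range(m):
            if is_medoid[j]:
                continue
            acc_all = 0.0
            for t in range(k):
                acc[t] = 0.0
            for o in range(m):
                doj = D[o, j]
                base = doj - d1[o]
                if base > 0.0:
                    base = 0.0
                acc_all += base
                alt = doj if doj < d2[o] else d2[o]
                acc[n1[o]] += alt - d1[o] - base
            for t in range(k):
                delta = acc_all + acc[t]
                if delta < best_delta:
                    best_delta = delta
                    best_t = t
                    best_j = j
        if best_t < 0:
            break
        is_medoid[medoids[best_t]] = False
        medoids[best_t] = best_j
        is_medoid[best_j] = True
    cost = 0.0
    for o in range(m):
        b = np.inf
        for t in range(k):
            d = D[o, medoids[t]]
            if d < b:
                b = d
        cost += b
    return cost


def _assign(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Nearest-medoid labels, 1-based; each medoid anchors its own cluster."""
    sub = D[:, medoids]  # (m, k)
    lab = np.argmin(sub, axis=1)
    lab[medoids] = np.arange(len(medoids))  # a medoid stays in its own cluster
    return lab + 1


def _validate_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ContractError(f"distance matrix of shape {D.shape} is not square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ContractError("distance matrix is not symmetric")
    if np.any(D < 0):
        raise ContractError("distance matrix has negative entries")
    if np.any(np.diag(D) != 0):
        raise ContractError("distance matrix diagonal must be zero")
    return (D + D.T) / 2.0


def kmedoids(D: np.ndarray, k: int, seed: int = 0, restarts: int = 20,
             node_index: int = -1) -> LayerPartition:
    """PAM k-medoids on a distance matrix.

    Restart 0 uses the deterministic greedy BUILD initialization; the
    remaining restarts draw k distinct random medoids.  Every restart then
    runs steepest-descent SWAP; the lowest-cost solution wins (ties go to
    the earlier restart), so the result is deterministic given ``seed``.
    """
    D = _validate_distance(D)
    m = D.shape[0]
    if not 2 <= k <= m:
        raise ValueError(f"need 2 <= k <= m, got k={k}, m={m}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if k == m:
        medoids = np.arange(m)
        return LayerPartition(node_index, k, np.arange(1, m + 1), medoids, 0.0)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    best_cost = np.inf
    best_medoids = None
    for r in range(restarts):
        if r == 0:
            medoids = _build_init(D, k)
        else:
            medoids = rng.choice(m, size=k, replace=False).astype(np.int64)
        cost = _swap_descent(D, medoids)
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_medoids = medoids.copy()
    best_medoids.sort()
    labels = _assign(D, best_medoids)
    return LayerPartition(node_index, k, labels, best_medoids, float(best_cost))


def derive_seed(seed: int, node: int, k: int) -> int:
    """Deterministic per-(node, k) sub-seed, independent of execution order."""
    ss = np.random.SeedSequence([int(seed), int(node), int(k)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def partition_ensemble(dstack: NodalDistanceStack, k_values,
                       seed: int = 0, restarts: int = 20) -> list[LayerPartition]:
    """One k-medoids partition per (node, k) pair, N x |k_values| in total."""
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be nonempty")
    m = dstack.m
    for k in k_values:
        if not 2 <= k <= m:
            raise ValueError(f"need 2 <= k <= m for every k, got k={k}, m={m}")
    parts = []
    for node in range(dstack.n_layers):
        D = dstack.layers[node]
        for k in k_values:
            parts.append(
                kmedoids(D, k, seed=derive_seed(seed, node, k),
                         restarts=restarts, node_index=node)
            )
    return parts
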