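"""Consensus matrix, permutation-null coassignment, and Louvain communities.

The consensus matrix C averages, over all (node, k) layer partitions, the
binary coassignment indicator "subjects alpha and beta share a cluster".
The null matrix P is the coassignment expected when cluster labels are
randomly permuted within each partition; under this ensemble P is uniform
off-diagonal with value mean_p sum_c n_c (n_c - 1) / (m (m - 1)).  The
modularity matrix B = C - P is handed directly to a Louvain routine that
accepts a modularity matrix (no internal null subtraction), maximizing

    Q = sum_{i != j} B_ij delta(c_i, c_j) / norm,

where norm defaults to the total off-diagonal consensus weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from conncluster.errors import ContractError
from conncluster.distance import NodalDistanceStack, all_nodal_distances
from conncluster.io import ConnectomeStack
from conncluster.layercluster import LayerPartition, partition_ensemble


@dataclass
class ConsensusMatrix:
    """m x m co-classification frequencies in [0, 1].

    Off-diagonal entries are exact multiples of 1 / ``n_partitions``; the
    diagonal is exactly 1.
    """

    values: np.ndarray
    n_partitions: int
    k_values: list[int] = field(default_factory=list)
    subjects: list[str] | None = None

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass
class CommunityResult:
    """Final subject communities from modularity maximization on B = C - P."""

    labels: np.ndarray           # 1-based, canonical (first-appearance order)
    modularity_value: float
    n_runs: int
    B: np.ndarray = field(repr=False)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def community_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


def _labels_of(p) -> np.ndarray:
    return p.labels if isinstance(p, LayerPartition) else np.asarray(p)


def coassignment(partition) -> np.ndarray:
    """Binary matrix: entry (a, b) is 1 iff a and b share a cluster label."""
    lab = _labels_of(partition)
    return (lab[:, None] == lab[None, :]).astype(float)


def consensus_matrix(partitions: list) -> ConsensusMatrix:
    """Entrywise mean of coassignment matrices over all partitions.

    Partitions from several k values are fused by including every (node, k)
    partition with equal weight in one mean.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    labels = [_labels_of(p) for p in partitions]
    ms = {len(l) for l in labels}
    if len(ms) > 1:
        raise ContractError(f"partitions over different subject counts: {sorted(ms)}")
    m = ms.pop()
    C = np.zeros((m, m))
    for lab in labels:
        C += lab[:, None] == lab[None, :]
    C /= len(labels)
    ks = sorted({p.k_requested for p in partitions if isinstance(p, LayerPartition)})
    return ConsensusMatrix(C, n_partitions=len(labels), k_values=ks)


def _pair_fraction(lab: np.ndarray) -> float:
    """Probability that a random ordered pair is coassigned: sum n_c(n_c-1)/(m(m-1))."""
    m = len(lab)
    _, counts = np.unique(lab, return_counts=True)
    return float(np.sum(counts * (counts - 1)) / (m * (m - 1)))


def expected_coassignment(partitions: list, mode: str = "analytic",
                          n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """Null coassignment matrix P under random label permutations.

    ``analytic`` computes the uniform off-diagonal value in closed form from
    cluster sizes; ``permutation`` estimates the same quantity by shuffling
    each partition's label vector ``n_perm`` times.  The diagonal is set to
    1 so that B = C - P has zero diagonal.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    labels = [_labels_of(p) for p in partitions]
    m = len(labels[0])
    if mode == "analytic":
        p = float(np.mean([_pair_fraction(lab) for lab in labels]))
        P = np.full((m, m), p)
    elif mode == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        acc = np.zeros((m, m))
        chunk = max(1, min(n_perm, 4_000_000 // (m * m)))
        for lab in labels:
            done = 0
            while done < n_perm:
                b = min(chunk, n_perm - done)
                perms = rng.permuted(np.tile(lab, (b, 1)), axis=1)
                acc += (perms[:, :, None] == perms[:, None, :]).sum(axis=0)
                done += b
        P = acc / (len(labels) * n_perm)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(P, 1.0)
    return P


def modularity_matrix(C, P: np.ndarray) -> np.ndarray:
    """B = C - P, entrywise; zero diagonal by the diag(P) = 1 convention."""
    Cv = C.values if isinstance(C, ConsensusMatrix) else np.asarray(C)
    P = np.asarray(P)
    if Cv.shape != P.shape:
        raise ContractError(f"shape mismatch: C is {Cv.shape}, P is {P.shape}")
    return Cv - P


def _modularity(B: np.ndarray, labels: np.ndarray, norm: float) -> float:
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    return float(B[same].sum() / norm)


def _local_move(M: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, bool]:
    """Louvain phase 1: greedy node moving on the (possibly aggregated) matrix."""
    n = M.shape[0]
    comm = np.arange(n)
    improved = False
    moved = True
    while moved:
        moved = False
        for v in order:
            w = np.zeros(n)
            np.add.at(w, comm, M[v])
            w[comm[v]] -= M[v, v]  # self-loop moves with v; not a gain anywhere
            target = int(np.argmax(w))
            if w[target] > w[comm[v]] + 1e-12 and target != comm[v]:
                comm[v] = target
                moved = True
                improved = True
    return comm, improved


def _aggregate(M: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, newlab = np.unique(comm, return_inverse=True)
    K = len(uniq)
    T = np.zeros((M.shape[0], K))
    T[np.arange(M.shape[0]), newlab] = 1.0
    return T.T @ M @ T, newlab


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel 1..K in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, l in enumerate(labels):
        if l not in mapping:
            mapping[l] = len(mapping) + 1
        out[i] = mapping[l]
    return out


def _local_move_from(M: np.ndarray, order: np.ndarray,
                     comm: np.ndarray) -> np.ndarray:
    """Greedy node moving started from a given assignment (for refinement)."""
    n = M.shape[0]
    comm = comm.copy()
    moved = True
    while moved:
        moved = False
        for v in order:
            w = np.zeros(n)
            np.add.at(w, comm, M[v])
            w[comm[v]] -= M[v, v]
            target = int(np.argmax(w))
            if w[target] > w[comm[v]] + 1e-12 and target != comm[v]:
                comm[v] = target
                moved = True
    return comm


def _louvain_once(B: np.ndarray, order: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    m = B.shape[0]
    M = B.copy()
    global_labels = np.arange(m)
    level_order = order
    while True:
        comm, improved = _local_move(M, level_order)
        if not improved:
            break
        M, newlab = _aggregate(M, comm)
        global_labels = newlab[comm[global_labels]]
        if M.shape[0] == 1:
            break
        level_order = rng.permutation(M.shape[0])
    return global_labels + 1


def louvain_communities(B: np.ndarray, runs: int = 20, seed: int = 0,
                        norm: float | None = None,
                        n_refine: int = 8) -> CommunityResult:
    """Louvain modularity maximization applied directly to a modularity matrix.

    The matrix B is treated as the full (signed) modularity matrix: the
    objective is Q = sum_{i != j} B_ij delta(c_i, c_j) / norm, with no
    further null-model subtraction.  Each run visits nodes in a different
    random order and is followed by ``n_refine`` iterated-local-search
    steps (perturb a random 20% of the labels, re-descend, keep if Q
    improves) to escape the plateaus of pure greedy node moving.  The
    best-Q run wins, ties broken by fewest communities then
    lexicographically smallest canonical label vector.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ContractError(f"B of shape {B.shape} is not square")
    if not np.allclose(B, B.T, atol=1e-8):
        raise ContractError("B must be symmetric")
    m = B.shape[0]
    if norm is None:
        norm = float(np.abs(B).sum() - np.abs(np.diag(B)).sum())
        if norm == 0.0:
            norm = 1.0
    if runs < 1:
        raise ValueError("runs must be >= 1")
    offdiag = B.copy()
    np.fill_diagonal(offdiag, 0.0)
    if np.all(offdiag == 0):
        return CommunityResult(np.ones(m, dtype=int), 0.0, runs, B)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    best: tuple | None = None
    n_move = max(1, int(round(0.2 * m)))
    for _ in range(runs):
        order = rng.permutation(m)
        labels0 = _louvain_once(B, order, rng) - 1
        q0 = _modularity(B, labels0, norm)
        for _ in range(n_refine):
            pert = labels0.copy()
            idx = rng.choice(m, n_move, replace=False)
            pert[idx] = rng.integers(0, m, n_move)
            cand = _local_move_from(B, rng.permutation(m), pert)
            qc = _modularity(B, cand, norm)
            if qc > q0 + 1e-12:
                labels0, q0 = cand, qc
        labels = _canonical(labels0 + 1)
        key = (-q0, len(np.unique(labels)), tuple(labels))
        if best is None or key < best[0]:
            best = (key, labels, q0)
    _, labels, q = best
    return CommunityResult(labels, q, runs, B)


@dataclass
class PipelineResult:
    """All artifacts of one consensus-clustering run."""

    dstack: NodalDistanceStack | None
    partitions: list[LayerPartition]
    consensus: ConsensusMatrix
    P: np.ndarray
    B: np.ndarray
    communities: CommunityResult


def consensus_pipeline(dstack: NodalDistanceStack, k_values=None,
                       seed: int = 0, restarts: int = 20,
                       louvain_runs: int = 20, null_mode: str = "analytic",
                       n_perm: int = 1000) -> PipelineResult:
    """Stages (b)-(d): layer k-medoids, consensus fusion, Louvain on B = C - P.

    Entry point for data that already lives in distance space (e.g., the
    toy-model stacks).
    """
    if k_values is None:
        k_values = range(2, min(21, dstack.m - 1) + 1)
    parts = partition_ensemble(dstack, k_values, seed=seed, restarts=restarts)
    C = consensus_matrix(parts)
    C.subjects = dstack.subjects
    perm_seed = int(np.random.SeedSequence([int(seed), 2]).generate_state(1)[0]
                    & 0x7FFFFFFF)
    P = expected_coassignment(parts, mode=null_mode, n_perm=n_perm,
                              seed=perm_seed)
    B = modularity_matrix(C, P)
    offdiag_weight = float(C.values.sum() - np.trace(C.values))
    louv_seed = int(np.random.SeedSequence([int(seed), 1]).generate_state(1)[0]
                    & 0x7FFFFFFF)
    comms = louvain_communities(B, runs=louvain_runs, seed=louv_seed,
                                norm=offdiag_weight if offdiag_weight > 0 else 1.0)
    return PipelineResult(dstack, parts, C, P, B, comms)


def run_pipeline(stack: ConnectomeStack, metric: str = "spearman_one_minus_r",
                 k_values=None, seed: int = 0, restarts: int = 20,
                 louvain_runs: int = 20, null_mode: str = "analytic",
                 n_perm: int = 1000,
                 keep_diagonal: bool = False) -> PipelineResult:
    """Full pipeline from a connectome stack: distances, then stages (b)-(d)."""
    dstack = all_nodal_distances(stack, metric=metric, keep_diagonal=keep_diagonal)
    return consensus_pipeline(dstack, k_values=k_values, seed=seed,
                              restarts=restarts, louvain_runs=louvain_runs,
                              null_mode=null_mode, n_perm=n_perm)
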