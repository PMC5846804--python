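"""Scoring recovered partitions and downstream analyses.

Covers the planted-partition accuracy statistic, the average-distance
k-medoids baseline, density thresholding of weighted networks, Pearson
similarity of consensus matrices, and community-vs-phenotype association
(Wilcoxon rank-sum with Bonferroni correction plus a shuffle null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import mannwhitneyu, pearsonr

from conncluster.errors import ContractError, UndefinedCorrelationError
from conncluster.consensus import CommunityResult, ConsensusMatrix
from conncluster.distance import NodalDistanceStack, average_distance
from conncluster.layercluster import LayerPartition, kmedoids


@dataclass
class AccuracyReport:
    """Planted-partition accuracy: sum over the M largest clusters of each
    cluster's best single-group overlap, divided by m."""

    accuracy: float
    M: int
    overlaps: list  # (cluster_label, best_group_label, overlap_count)

    def __float__(self) -> float:
        return self.accuracy


def _as_labels(x) -> np.ndarray:
    if isinstance(x, (CommunityResult, LayerPartition)):
        return np.asarray(x.labels, dtype=int)
    if hasattr(x, "labels"):
        return np.asarray(x.labels, dtype=int)
    return np.asarray(x, dtype=int)


def accuracy(truth, clusters) -> AccuracyReport:
    """Score a recovered partition against planted groups.

    With M = min(number of true groups, number of clusters), the M largest
    clusters (ties broken by smallest cluster label) each contribute the
    size of their largest intersection with any single group; the sum is
    divided by m.  No one-to-one group/cluster matching is imposed, so a
    group may be the best match of several clusters.
    """
    g = _as_labels(truth)
    c = _as_labels(clusters)
    if len(g) != len(c):
        raise ContractError(f"label length mismatch: {len(g)} vs {len(c)}")
    m = len(g)
    groups = np.unique(g)
    clabels, csizes = np.unique(c, return_counts=True)
    M = min(len(groups), len(clabels))
    # largest M clusters; ties at equal size go to the smaller label
    order = np.lexsort((clabels, -csizes))
    chosen = clabels[order[:M]]
    overlaps = []
    total = 0
    for cl in chosen:
        inter = [(int(np.sum((c == cl) & (g == gl))), -gl) for gl in groups]
        best_count, neg_gl = max(inter)
        overlaps.append((int(cl), int(-neg_gl), best_count))
        total += best_count
    return AccuracyReport(total / m, M, overlaps)


def matched_accuracy(truth, clusters) -> float:
    """One-to-one (Hungarian) matched accuracy; a stricter alternative score."""
    g = _as_labels(truth)
    c = _as_labels(clusters)
    if len(g) != len(c):
        raise ContractError(f"label length mismatch: {len(g)} vs {len(c)}")
    groups = np.unique(g)
    clabels = np.unique(c)
    cost = np.zeros((len(clabels), len(groups)))
    for i, cl in enumerate(clabels):
        for j, gl in enumerate(groups):
            cost[i, j] = -np.sum((c == cl) & (g == gl))
    rows, cols = linear_sum_assignment(cost)
    return float(-cost[rows, cols].sum() / len(g))


def baseline_average_kmedoids(dstack: NodalDistanceStack, k: int,
                              seed: int = 0, restarts: int = 20) -> LayerPartition:
    """The standard comparison: k-medoids on the node-averaged distance matrix."""
    return kmedoids(average_distance(dstack), k, seed=seed, restarts=restarts)


def threshold_density(A: np.ndarray, density: float,
                      absolute: bool = False) -> np.ndarray:
    """Retain the ceil(density * E) largest off-diagonal entries (E = m(m-1)/2).

    Retained entries keep their weights; all other off-diagonal entries are
    zeroed.  Ties at the cutoff keep the lower (row, col) pairs.  Ranking is
    by raw signed value unless ``absolute`` is set.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ContractError(f"matrix of shape {A.shape} is not square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ContractError("matrix must be symmetric")
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    m = A.shape[0]
    rows, cols = np.triu_indices(m, k=1)
    vals = A[rows, cols]
    rank_vals = np.abs(vals) if absolute else vals
    n_keep = int(np.ceil(density * len(vals)))
    order = np.lexsort((cols, rows, -rank_vals))  # value desc, then (row, col) asc
    keep = order[:n_keep]
    out = np.zeros_like(A)
    out[rows[keep], cols[keep]] = vals[keep]
    out += out.T
    out[np.diag_indices(m)] = np.diag(A)
    return out


def consensus_similarity(C1, C2) -> float:
    """Pearson correlation of the two matrices' upper-triangle entries."""
    A = C1.values if isinstance(C1, ConsensusMatrix) else np.asarray(C1)
    B = C2.values if isinstance(C2, ConsensusMatrix) else np.asarray(C2)
    if A.shape != B.shape:
        raise ContractError(f"shape mismatch: {A.shape} vs {B.shape}")
    iu = np.triu_indices(A.shape[0], k=1)
    x, y = A[iu], B[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "consensus similarity undefined: constant off-diagonal entries"
        )
    return float(pearsonr(x, y).statistic)


_EXACT_MAX_N = 25  # per-group size below which the exact rank-sum null is used


def phenotype_association(communities, table, n_shuffle: int = 500,
                          seed: int = 0) -> pd.DataFrame:
    """Compare phenotype variables between two subject communities.

    With exactly two communities they are compared directly; with more, the
    largest community is compared against all others pooled.  Per variable:
    a two-sided Wilcoxon rank-sum test (exact null when both groups have
    at most 25 members and no ties, normal approximation with tie
    correction otherwise), Bonferroni correction across variables, and the
    quantiles of a shuffle null of the group-mean difference obtained by
    permuting the community/phenotype pairing ``n_shuffle`` times.
    """
    labels = _as_labels(communities)
    data = table.data if hasattr(table, "data") else pd.DataFrame(table)
    if len(labels) != len(data):
        raise ContractError(
            f"{len(labels)} community labels for {len(data)} phenotype rows"
        )
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two communities to compare")
    if len(uniq) == 2:
        in_first = labels == uniq[0]
    else:  # largest community vs the rest pooled
        in_first = labels == uniq[np.argmax(counts)]
    if in_first.sum() < 2 or (~in_first).sum() < 2:
        raise ValueError("each compared group needs at least 2 members")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    n_vars = data.shape[1]
    rows = []
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        a, b = x[ok & in_first], x[ok & ~in_first]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"variable {col!r}: a group has < 2 observed values")
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = ("exact"
                  if max(len(a), len(b)) <= _EXACT_MAX_N and not has_ties
                  else "asymptotic")
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        obs_diff = float(a.mean() - b.mean())
        null = np.empty(n_shuffle)
        xo = x[ok]
        mask = in_first[ok]
        for s in range(n_shuffle):
            perm = rng.permutation(xo)
            null[s] = perm[mask].mean() - perm[~mask].mean()
        q = np.quantile(null, [0.025, 0.25, 0.5, 0.75, 0.975])
        rows.append({
            "variable": col,
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "p_bonferroni": min(1.0, float(res.pvalue) * n_vars),
            "mean_difference": obs_diff,
            "null_q025": q[0], "null_q25": q[1], "null_q50": q[2],
            "null_q75": q[3], "null_q975": q[4],
            "method": method,
        })
    return pd.DataFrame(rows).set_index("variable")
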