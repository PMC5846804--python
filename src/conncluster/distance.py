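"""Per-node inter-subject distance layers.

For node i, each subject contributes its nodal connectivity pattern A(i, :).
The distance between two subjects at node i is 1 - r with r the Spearman
rank correlation of their patterns (default), or sqrt(2 (1 - r)) with r the
Pearson correlation.  The N node-wise m x m distance matrices form the
layers of a multilayer subject-similarity network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from conncluster.errors import ContractError, UndefinedCorrelationError
from conncluster.io import ConnectomeStack

METRICS = ("spearman_one_minus_r", "pearson_sqrt")


@dataclass
class NodalDistanceStack:
    """N layers of m x m inter-subject distances, one layer per node.

    Attributes
    ----------
    layers : ndarray, shape (N, m, m)
        Symmetric, zero-diagonal, nonnegative distance matrices.
    metric : str
        ``"spearman_one_minus_r"`` or ``"pearson_sqrt"``.
    subjects : list of str, optional
        Subject identifiers in layer row/column order.
    """

    layers: np.ndarray
    metric: str = "spearman_one_minus_r"
    subjects: list[str] | None = None

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise ContractError(
                f"expected an (N, m, m) array, got shape {self.layers.shape}"
            )

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def m(self) -> int:
        return self.layers.shape[1]


def _nodal_patterns(stack: ConnectomeStack, node: int,
                    keep_diagonal: bool) -> np.ndarray:
    """Rows A(node, :) for all subjects, self-entry removed unless kept."""
    n = stack.n_nodes
    if not 0 <= node < n:
        raise IndexError(f"node {node} out of range for N={n}")
    X = stack.matrices[:, node, :]
    if not keep_diagonal:
        X = np.delete(X, node, axis=1)
    return X


def _check_variance(X: np.ndarray, stack: ConnectomeStack, node: int) -> None:
    const = np.ptp(X, axis=1) == 0
    if np.any(const):
        bad = [stack.subjects[i] for i in np.nonzero(const)[0]]
        raise UndefinedCorrelationError(
            f"constant nodal pattern at node {node} for subject(s) "
            f"{', '.join(bad)}: correlation undefined"
        )


def _corr_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    R = (Xc @ Xc.T) / np.outer(norms, norms)
    return np.clip(R, -1.0, 1.0)


def nodal_distance(stack: ConnectomeStack, node: int,
                   metric: str = "spearman_one_minus_r",
                   keep_diagonal: bool = False) -> np.ndarray:
    """Inter-subject distance matrix for one node.

    Parameters
    ----------
    stack : ConnectomeStack
    node : int
        Node index, 0-based.
    metric : str
        ``"spearman_one_minus_r"``: d = 1 - Spearman r (ties by average
        ranks).  ``"pearson_sqrt"``: d = sqrt(2 (1 - Pearson r)), a Euclidean
        embedding of the standardized patterns.
    keep_diagonal : bool
        If False (default), the node's own entry A(i, i) is removed from
        both patterns before correlating: it is constant across nodes of a
        correlation matrix and only corrupts rank ties.

    Returns
    -------
    ndarray, shape (m, m)
        Symmetric, zero diagonal; entries in [0, 2].
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = _nodal_patterns(stack, node, keep_diagonal)
    _check_variance(X, stack, node)
    if metric == "spearman_one_minus_r":
        ranks = rankdata(X, axis=1)
        D = 1.0 - _corr_rows(ranks)
    else:
        R = _corr_rows(X)
        D = np.sqrt(np.maximum(2.0 * (1.0 - R), 0.0))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def all_nodal_distances(stack: ConnectomeStack,
                        metric: str = "spearman_one_minus_r",
                        keep_diagonal: bool = False) -> NodalDistanceStack:
    """Distance layers for every node, in node order."""
    layers = np.empty((stack.n_nodes, stack.m, stack.m))
    for node in range(stack.n_nodes):
        try:
            layers[node] = nodal_distance(stack, node, metric, keep_diagonal)
        except UndefinedCorrelationError:
            raise
        except Exception as exc:  # re-tag with the node index
            raise type(exc)(f"node {node}: {exc}") from exc
    return NodalDistanceStack(layers, metric=metric, subjects=list(stack.subjects))


def average_distance(dstack: NodalDistanceStack) -> np.ndarray:
    """Entrywise mean of all layers (the baseline's single distance matrix)."""
    if dstack.n_layers == 0:
        raise ValueError("cannot average an empty distance stack")
    D = dstack.layers.mean(axis=0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D
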