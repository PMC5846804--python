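"""Synthetic multilayer distance stacks with planted group structure.

The benchmark simulates m subjects split into groups and described by
n_nodes distance layers.  In an *informative* layer, within-group pairs
draw their distance uniformly from ``within_interval`` and between-group
pairs from ``between_interval``; in an uninformative layer every pair draws
from ``between_interval``.  Each unordered pair is sampled once and
mirrored, so layers are symmetric with zero diagonal.  The model lives
directly in distance space: the pipeline is entered at the layer-clustering
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from conncluster.distance import NodalDistanceStack

# Default parameterization: 100 subjects in 4 groups of 25, 30 nodes of
# which 10 informative; within-group distances uniform on [0.1, 0.4),
# between-group and uninformative entries uniform on [0.2, 0.4).
_DEFAULT_GROUPS = (25, 25, 25, 25)


@dataclass
class ToySpec:
    """Parameters of the planted-group distance-stack simulator."""

    group_sizes: tuple = _DEFAULT_GROUPS
    n_nodes: int = 30
    n_informative: int = 10
    within_interval: tuple = (0.1, 0.4)
    between_interval: tuple = (0.2, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = tuple(int(s) for s in self.group_sizes)
        if any(s < 1 for s in self.group_sizes) or len(self.group_sizes) < 1:
            raise ValueError(f"invalid group sizes {self.group_sizes}")
        if not 0 <= self.n_informative <= self.n_nodes:
            raise ValueError(
                f"need 0 <= n_informative <= n_nodes, got "
                f"{self.n_informative} / {self.n_nodes}"
            )
        for lo, hi in (self.within_interval, self.between_interval):
            if not (0 <= lo < hi):
                raise ValueError(f"invalid interval [{lo}, {hi})")

    @property
    def m(self) -> int:
        return sum(self.group_sizes)

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted group label (1-based) for each subject."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_groups(self) -> int:
        return len(np.unique(self.labels))


def simulate(spec: ToySpec) -> tuple[NodalDistanceStack, GroundTruth]:
    """Draw one distance stack and its planted groups, deterministic in seed."""
    m = spec.m
    labels = np.repeat(np.arange(1, spec.n_groups + 1), spec.group_sizes)
    iu = np.triu_indices(m, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    wlo, whi = spec.within_interval
    blo, bhi = spec.between_interval
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF]))
    layers = np.zeros((spec.n_nodes, m, m))
    for node in range(spec.n_nodes):
        u = rng.random(len(iu[0]))  # one draw per unordered pair
        if node < spec.n_informative:
            vals = np.where(same, wlo + u * (whi - wlo), blo + u * (bhi - blo))
        else:
            vals = blo + u * (bhi - blo)
        layers[node][iu] = vals
        layers[node] += layers[node].T
    return (
        NodalDistanceStack(layers, metric="toy",
                           subjects=[f"sub{i:03d}" for i in range(m)]),
        GroundTruth(labels),
    )


_PRESETS = {
    "fig3_4groups": dict(group_sizes=(25, 25, 25, 25), n_nodes=30,
                         n_informative=10, within_interval=(0.1, 0.4),
                         between_interval=(0.2, 0.4)),
    "fig4_4groups": dict(group_sizes=(25, 25, 25, 25), n_nodes=30,
                         n_informative=10, within_interval=(0.1, 0.4),
                         between_interval=(0.15, 0.4)),
    "fig4_2groups": dict(group_sizes=(50, 50), n_nodes=30,
                         n_informative=10, within_interval=(0.1, 0.4),
                         between_interval=(0.15, 0.4)),
}


def variant_spec(preset: str, seed: int = 0, **overrides) -> ToySpec:
    """A named benchmark parameterization; overrides apply on top."""
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    params = {**_PRESETS[preset], "seed": seed, **overrides}
    return ToySpec(**params)
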