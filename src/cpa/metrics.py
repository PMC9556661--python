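"""The three connectivity-profile misconfiguration metrics.

A *fingerprint* is the length-T vector of Fisher-Z connectivity strengths
between one striatal voxel and T frontal cortical targets.  Differences
between two fingerprints are quantified along three dissociable dimensions:

``aggregate_divergence``
    Sum of absolute differences of matched connections — total strength
    change, blind to ordering.
``rank_order_misarrangement``
    Spearman-footrule distance between the strength rank vectors — how far
    the ordering of strongest-to-weakest connections was reshuffled,
    invariant to any strictly monotone transform of either profile.
``entropy_shift``
    Absolute difference of the Shannon entropies of the normalised absolute
    profiles — change in how strength is concentrated in a few connections
    versus spread across many, invariant to rescaling either profile.

All scalar operations have vectorised counterparts operating on
(n_voxels, T) profile matrices; ``metric_map`` applies a metric at every
in-mask voxel of a grid-aligned pair of fingerprint maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import VoxelGrid

MetricName = Literal["aggregate_divergence", "rank_misarrangement",
                     "entropy_shift"]
METRICS: tuple[str, ...] = ("aggregate_divergence", "rank_misarrangement",
                            "entropy_shift")


@dataclass
class MetricMap:
    """Per-voxel scalar field for one metric and one comparison."""

    metric: str
    values: np.ndarray
    comparison: tuple[str, str]
    grid: VoxelGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.values.shape != (self.grid.n_voxels,):
            raise ValueError("values not aligned to grid")
        if np.any(self.values < 0):
            raise ValueError("metric values must be non-negative")


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    return a, b


# ---------------------------------------------------------------------------
# aggregate divergence
# ---------------------------------------------------------------------------

def aggregate_divergence(a: np.ndarray, b: np.ndarray) -> float:
    """Sum_i |a_i - b_i| between two matched fingerprints."""
    a, b = _check_pair(a, b)
    return float(np.abs(a - b).sum())


def aggregate_divergence_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A, B = _check_pair(A, B)
    return np.abs(A - B).sum(axis=-1)


# ---------------------------------------------------------------------------
# rank order misarrangement
# ---------------------------------------------------------------------------

def rank_vector(a: np.ndarray) -> np.ndarray:
    """Ranks 1..T ascending with connection strength (1 = weakest).

    Ties break deterministically by target index: the lower index gets the
    lower rank.
    """
    return rank_matrix(np.atleast_2d(np.asarray(a, dtype=float)))[0]


def rank_matrix(A: np.ndarray) -> np.ndarray:
    """Row-wise rank vectors of an (..., T) profile array."""
    A = np.asarray(A, dtype=float)
    order = np.argsort(A, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order,
                      np.broadcast_to(np.arange(1, A.shape[-1] + 1),
                                      A.shape).copy(), axis=-1)
    return ranks


def rank_order_misarrangement(a: np.ndarray, b: np.ndarray) -> int:
    """Spearman footrule distance Sum_i |rank_a(i) - rank_b(i)|."""
    a, b = _check_pair(a, b)
    return int(np.abs(rank_vector(a) - rank_vector(b)).sum())


def rank_misarrangement_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A, B = _check_pair(A, B)
    return np.abs(rank_matrix(A) - rank_matrix(B)).sum(axis=-1)


# ---------------------------------------------------------------------------
# profile entropy / entropy shift
# ---------------------------------------------------------------------------

def profile_entropy(a: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy (nats by default) of the normalised absolute profile.

    p_i = |a_i| / Sum_j |a_j|; H = -Sum p_i log p_i with 0 log 0 = 0.
    Raises for an all-zero profile, where the distribution is undefined.
    ``base`` switches the logarithm base (e.g. 2); natural log by default.
    """
    H = entropy_matrix(np.atleast_2d(np.asarray(a, dtype=float)), base=base)
    return float(H[0])


def entropy_matrix(A: np.ndarray, base: float | None = None) -> np.ndarray:
    A = np.abs(np.asarray(A, dtype=float))
    tot = A.sum(axis=-1, keepdims=True)
    if np.any(tot == 0):
        raise ValueError("entropy undefined for an all-zero profile")
    p = A / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    H = -terms.sum(axis=-1)
    if base is not None:
        H = H / np.log(base)
    return H


def entropy_shift(a: np.ndarray, b: np.ndarray,
                  base: float | None = None) -> float:
    """|H(a) - H(b)|."""
    a, b = _check_pair(a, b)
    return float(abs(profile_entropy(a, base=base)
                     - profile_entropy(b, base=base)))


def entropy_shift_matrix(A: np.ndarray, B: np.ndarray,
                         base: float | None = None) -> np.ndarray:
    A, B = _check_pair(A, B)
    return np.abs(entropy_matrix(A, base=base) - entropy_matrix(B, base=base))


# ---------------------------------------------------------------------------
# voxel-wise application
# ---------------------------------------------------------------------------

_MATRIX_FNS = {
    "aggregate_divergence": aggregate_divergence_matrix,
    "rank_misarrangement": rank_misarrangement_matrix,
    "entropy_shift": entropy_shift_matrix,
}


def metric_values(A: np.ndarray, B: np.ndarray, metric: str,
                  entropy_base: float | None = None) -> np.ndarray:
    """Apply one metric row-wise to two (n_voxels, T) fingerprint maps."""
    if metric not in _MATRIX_FNS:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "entropy_shift":
        return entropy_shift_matrix(A, B, base=entropy_base)
    return np.asarray(_MATRIX_FNS[metric](A, B), dtype=float)


def metric_map(map_a: np.ndarray, map_b: np.ndarray, metric: str,
               grid: VoxelGrid, comparison: tuple[str, str] = ("A", "B"),
               entropy_base: float | None = None) -> MetricMap:
    """Voxel-wise metric between two grid-aligned group fingerprint maps."""
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    if map_a.shape != map_b.shape:
        raise ValueError("fingerprint maps differ in shape")
    if map_a.shape[0] != grid.n_voxels:
        raise ValueError("fingerprint maps not aligned to grid")
    values = metric_values(map_a, map_b, metric, entropy_base=entropy_base)
    return MetricMap(metric=metric, values=values, comparison=comparison,
                     grid=grid)
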