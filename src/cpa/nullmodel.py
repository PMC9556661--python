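"""Normative permutation nulls and significance thresholds.

Statistical assessment of a misconfiguration metric needs a reference
distribution of the values the metric takes *without* the group difference
of interest.  That reference is built by repeatedly splitting a matched
normative cohort into pseudo-groups of the empirical sample sizes,
computing pseudo-group-average fingerprint maps and the voxel-wise metric,
and pooling values across voxels and permutations.  The voxel-wise
significance threshold is the empirical (1 - alpha) quantile of the pooled
null; a cluster-extent null records the maximum suprathreshold cluster
size per permutation and yields the extent threshold that controls
family-wise error.

Throughout the package a value is significant when it is *greater than or
equal to* the derived threshold; for integer-valued metrics this is the
convention under which null exceedance stays close to alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .connectivity import ZScoreMap
from .io import VoxelGrid
from .metrics import METRICS, metric_values

DEFAULT_N_PERM = 1000
DEFAULT_ALPHA = 1e-3
DEFAULT_ALPHA_FWE = 0.05
DEFAULT_CONNECTIVITY = 6

#: pooled null must contain at least this many samples per unit of 1/alpha
MIN_SAMPLES_PER_INV_ALPHA = 10


@dataclass
class NullDistribution:
    """Pooled permutation null of one metric with its derived threshold."""

    metric: str
    samples: np.ndarray
    n_permutations: int
    group_sizes: tuple[int, int]
    alpha: float
    threshold: float
    seed: int

    def save(self, csv_path: str | Path, json_path: str | Path,
             max_samples: int | None = 100_000) -> None:
        s = self.samples
        if max_samples is not None and s.size > max_samples:
            step = int(np.ceil(s.size / max_samples))
            s = np.sort(s)[::step]
        pd.DataFrame({"null_value": s}).to_csv(csv_path, index=False)
        meta = {"metric": self.metric, "n_permutations": self.n_permutations,
                "group_sizes": list(self.group_sizes), "alpha": self.alpha,
                "threshold": self.threshold, "seed": self.seed,
                "n_samples": int(self.samples.size)}
        Path(json_path).write_text(json.dumps(meta, indent=2))


@dataclass
class ClusterNull:
    """Permutation distribution of the maximum suprathreshold cluster size."""

    metric: str
    max_cluster_sizes: np.ndarray
    alpha_fwe: float
    k_threshold: int
    voxel_threshold: float
    seed: int


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D adjacency structuring element for 6/18/26-connectivity."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------

def permutation_splits(n_subjects: int, n_a: int, n_b: int, n_perm: int,
                       seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random pseudo-group partitions of the normative pool.

    Each permutation draws, without replacement, disjoint index sets of
    sizes ``n_a`` and ``n_b``; permutations are independent draws,
    reproducible under ``seed``.
    """
    if n_a + n_b > n_subjects:
        raise ValueError(f"cannot split {n_subjects} subjects into "
                         f"pseudo-groups of {n_a} + {n_b}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_perm):
        idx = rng.permutation(n_subjects)
        splits.append((np.sort(idx[:n_a]), np.sort(idx[n_a:n_a + n_b])))
    return splits


def _stack(zmaps: list[ZScoreMap]) -> np.ndarray:
    grids = [m.grid for m in zmaps]
    if any(not grids[0].compatible_with(g) for g in grids[1:]):
        raise ValueError("normative maps do not share a voxel grid")
    T = {m.n_targets for m in zmaps}
    if len(T) != 1:
        raise ValueError("normative maps differ in target count")
    return np.stack([m.values for m in zmaps])


def null_metric_samples(normative_zmaps: list[ZScoreMap], metric: str,
                        n_a: int, n_b: int, n_perm: int, seed: int,
                        entropy_base: float | None = None) -> np.ndarray:
    """(n_perm, n_voxels) pseudo-group metric values under permutation."""
    Z = _stack(normative_zmaps)
    splits = permutation_splits(Z.shape[0], n_a, n_b, n_perm, seed)
    out = np.empty((n_perm, Z.shape[1]))
    for i, (ia, ib) in enumerate(splits):
        A = Z[ia].mean(axis=0)
        B = Z[ib].mean(axis=0)
        out[i] = metric_values(A, B, metric, entropy_base=entropy_base)
    return out


def critical_value(samples: np.ndarray, alpha: float) -> float:
    """Empirical (1 - alpha) critical value of a permutation null.

    Significance downstream uses the ``value >= threshold`` rule, so the
    threshold is chosen as the support value whose empirical null
    exceedance under that rule is closest to ``alpha`` on a log scale.
    For a continuous metric this coincides with the empirical (1 - alpha)
    quantile (exceedance exactly alpha up to sample granularity); for an
    integer-valued metric it selects the best-calibrated achievable atom
    instead of overshooting or undershooting on a tie.  Degenerate
    all-equal samples yield that single value.
    """
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    uniq = np.unique(s)
    frac_ge = 1.0 - np.searchsorted(s, uniq, side="left") / s.size
    # guard the log for support values never attained (frac_ge == 0 cannot
    # occur for members of the support)
    dist = np.abs(np.log(frac_ge) - np.log(alpha))
    return float(uniq[int(np.argmin(dist))])


def build_null(normative_zmaps: list[ZScoreMap], metric: str, n_a: int,
               n_b: int, n_perm: int = DEFAULT_N_PERM,
               alpha: float = DEFAULT_ALPHA, seed: int = 0,
               entropy_base: float | None = None) -> NullDistribution:
    """Pooled normative null and voxel-wise threshold for one metric.

    Null values are pooled across voxels and permutations into a single
    per-metric distribution; the threshold is its empirical (1 - alpha)
    quantile in the :func:`critical_value` convention.  The pooled sample
    count must be at least 10 / alpha.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    samples = null_metric_samples(normative_zmaps, metric, n_a, n_b, n_perm,
                                  seed, entropy_base=entropy_base).ravel()
    if samples.size < MIN_SAMPLES_PER_INV_ALPHA / alpha:
        raise ValueError(
            f"insufficient null samples ({samples.size}) for alpha={alpha}; "
            f"need at least {MIN_SAMPLES_PER_INV_ALPHA / alpha:.0f}")
    threshold = critical_value(samples, alpha)
    return NullDistribution(metric=metric, samples=samples,
                            n_permutations=n_perm, group_sizes=(n_a, n_b),
                            alpha=alpha, threshold=threshold, seed=seed)


def per_voxel_thresholds(normative_zmaps: list[ZScoreMap], metric: str,
                         n_a: int, n_b: int, n_perm: int, alpha: float,
                         seed: int,
                         entropy_base: float | None = None) -> np.ndarray:
    """Voxel-specific (1 - alpha) null quantiles (the non-pooled mode)."""
    samples = null_metric_samples(normative_zmaps, metric, n_a, n_b, n_perm,
                                  seed, entropy_base=entropy_base)
    return np.array([critical_value(samples[:, v], alpha)
                     for v in range(samples.shape[1])])


def calibration_check(build_samples: np.ndarray, fresh_samples: np.ndarray,
                      alpha: float, n_boot: int = 200, seed: int = 0) -> dict:
    """Calibration diagnostics of a derived threshold on fresh null data.

    ``build_samples`` and ``fresh_samples`` are (n_perm, n_voxels) null
    metric values.  The threshold is derived from the pooled build
    samples; the empirical exceedance rate (>= rule) is measured on the
    pooled fresh samples.  The Monte-Carlo standard error of that rate
    combines two terms, both respecting that the permutation — not the
    voxel — is the independent sampling unit (voxel-wise null values
    within one permutation are correlated through the shared pseudo-group
    split and session time series):

    * fresh-side: cluster-robust SE of the mean per-permutation
      exceedance fraction;
    * build-side: a cluster bootstrap over build permutations of the
      threshold, propagated to the fresh exceedance rate.

    Returns dict(threshold, rate, se_fresh, se_threshold, se_total).
    """
    rng = np.random.default_rng(seed)
    build = np.asarray(build_samples, dtype=float)
    fresh = np.asarray(fresh_samples, dtype=float)
    threshold = critical_value(build.ravel(), alpha)
    per_perm = (fresh >= threshold).mean(axis=1)
    rate = float(per_perm.mean())
    se_fresh = float(per_perm.std(ddof=1) / np.sqrt(per_perm.shape[0]))

    fresh_sorted = np.sort(fresh.ravel())
    n_fresh = fresh_sorted.size
    boot_rates = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, build.shape[0], size=build.shape[0])
        thr_b = critical_value(build[idx].ravel(), alpha)
        boot_rates[b] = 1.0 - np.searchsorted(fresh_sorted, thr_b,
                                              side="left") / n_fresh
    se_thr = float(boot_rates.std(ddof=1))
    return {"threshold": threshold, "rate": rate, "se_fresh": se_fresh,
            "se_threshold": se_thr,
            "se_total": float(np.hypot(se_fresh, se_thr))}


# ---------------------------------------------------------------------------
# cluster-extent null
# ---------------------------------------------------------------------------

def max_cluster_size(volume: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(volume, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def k_threshold_from_max_sizes(max_sizes: np.ndarray,
                               alpha_fwe: float) -> int:
    """Smallest k whose exceedance fraction P(max size >= k) is below
    alpha_fwe."""
    max_sizes = np.asarray(max_sizes)
    for k in range(1, int(max_sizes.max(initial=0)) + 2):
        if (max_sizes >= k).mean() < alpha_fwe:
            return k
    return int(max_sizes.max(initial=0)) + 1


def cluster_size_null(normative_zmaps: list[ZScoreMap], metric: str,
                      voxel_threshold: float, n_a: int, n_b: int,
                      n_perm: int = DEFAULT_N_PERM,
                      alpha_fwe: float = DEFAULT_ALPHA_FWE,
                      connectivity: int = DEFAULT_CONNECTIVITY, seed: int = 0,
                      entropy_base: float | None = None) -> ClusterNull:
    """Permutation null of the maximum suprathreshold cluster extent.

    Per permutation the pseudo-group metric map is thresholded at
    ``voxel_threshold`` (>=), connected components are labelled under the
    chosen connectivity, and the maximum cluster size recorded.
    ``k_threshold`` is the smallest extent whose null exceedance fraction
    falls below ``alpha_fwe``; clusters of at least ``k_threshold`` voxels
    control family-wise error at that level.
    """
    grid: VoxelGrid = normative_zmaps[0].grid
    samples = null_metric_samples(normative_zmaps, metric, n_a, n_b, n_perm,
                                  seed, entropy_base=entropy_base)
    structure = connectivity_structure(connectivity)
    max_sizes = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        vol = grid.embed(samples[i] >= voxel_threshold, background=0.0) > 0
        max_sizes[i] = max_cluster_size(vol, structure)
    k_thr = k_threshold_from_max_sizes(max_sizes, alpha_fwe)
    return ClusterNull(metric=metric, max_cluster_sizes=max_sizes,
                       alpha_fwe=alpha_fwe, k_threshold=k_thr,
                       voxel_threshold=voxel_threshold, seed=seed)
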