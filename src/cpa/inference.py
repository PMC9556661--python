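"""Thresholding, clustering, contrasts and group statistics.

Empirical metric maps are thresholded voxel-wise at the normative null
threshold, grouped into connected components, and filtered by cluster
extent.  Within-subject state effects are assessed with voxel-wise paired
t-tests on subject-level metric maps.  Per-target rank differences are
tested against the permutation machinery's rank-difference null.  No
cross-metric multiple-comparison correction is applied: each metric is
thresholded against its own null, and overlap between metric-specific
significance masks is itself a reported quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .connectivity import ZScoreMap
from .io import SubjectRecord, VoxelGrid
from .metrics import MetricMap, metric_values, rank_matrix, rank_vector
from .nullmodel import connectivity_structure, permutation_splits

logger = logging.getLogger("cpa")

DEFAULT_MIN_RANK_DIFF = 5

CLUSTER_COLUMNS = ("cluster_id", "metric", "comparison", "size_k",
                   "peak_value", "peak_x_mm", "peak_y_mm", "peak_z_mm")


@dataclass
class SubjectMetricMap:
    """Per-subject, per-state metric map against a reference group average."""

    subject_id: str
    state: str
    metric: str
    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_voxels,):
            raise ValueError("values not aligned to grid")
        if np.any(self.values < 0):
            raise ValueError("metric values must be non-negative")


def empty_cluster_table() -> pd.DataFrame:
    return pd.DataFrame(columns=list(CLUSTER_COLUMNS))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def threshold_and_cluster(
    mmap: MetricMap,
    voxel_threshold: float,
    k_threshold: int,
    connectivity: int = 6,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster table and binary significance mask of one metric map.

    Voxels with value >= ``voxel_threshold`` form candidate clusters under
    the chosen connectivity; clusters with size strictly greater than
    ``k_threshold`` are retained (the printed extent rule "k > 7" keeps
    clusters of 8 or more).  Cluster peaks are reported in world (mm)
    coordinates; peak ties break to the lowest lexicographic voxel index.
    """
    if voxel_threshold < 0 or k_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    grid = mmap.grid
    supra = mmap.values >= voxel_threshold
    vol = grid.embed(supra, background=0.0) > 0
    labels, n = ndimage.label(vol, structure=connectivity_structure(connectivity))
    label_per_voxel = labels[tuple(grid.mask_indices.T)]
    rows, sig = [], np.zeros(grid.n_voxels, dtype=bool)
    cluster_id = 0
    for lab in range(1, n + 1):
        members = np.flatnonzero(label_per_voxel == lab)
        size = members.size
        if size <= k_threshold:
            continue
        cluster_id += 1
        sig[members] = True
        vals = mmap.values[members]
        # mask_indices are lexicographically sorted, so among ties the first
        # argmax is the lowest voxel index
        peak_voxel = grid.mask_indices[members[int(np.argmax(vals))]]
        world = grid.world_coords(peak_voxel)[0]
        rows.append({
            "cluster_id": cluster_id, "metric": mmap.metric,
            "comparison": "_vs_".join(mmap.comparison), "size_k": size,
            "peak_value": float(vals.max()), "peak_x_mm": world[0],
            "peak_y_mm": world[1], "peak_z_mm": world[2],
        })
    table = pd.DataFrame(rows, columns=list(CLUSTER_COLUMNS))
    return table, sig


# ---------------------------------------------------------------------------
# subject-level maps and the state contrast
# ---------------------------------------------------------------------------

def subject_metric_maps(subject_zmap: ZScoreMap, reference_group_map: np.ndarray,
                        metric: str,
                        entropy_base: float | None = None) -> SubjectMetricMap:
    """One subject's metric map against a reference group-average map."""
    ref = np.asarray(reference_group_map, dtype=float)
    if ref.shape != subject_zmap.values.shape:
        raise ValueError("reference map shape does not match subject map")
    values = metric_values(subject_zmap.values, ref, metric,
                           entropy_base=entropy_base)
    return SubjectMetricMap(subject_id=subject_zmap.subject_id,
                            state=subject_zmap.state, metric=metric,
                            values=values, grid=subject_zmap.grid)


def paired_state_contrast(
    maps_sated: list[SubjectMetricMap],
    maps_abstinent: list[SubjectMetricMap],
    voxel_p: float = 1e-3,
    k_threshold: int = 7,
    connectivity: int = 6,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Voxel-wise paired t-test of abstinent minus sated subject maps.

    Returns (cluster table of t statistics, signed t map, significance
    mask).  Voxels with zero within-pair variance have no defined t and are
    skipped with a warning.  Clusters form on |t| voxels with two-sided
    p < ``voxel_p`` and must exceed ``k_threshold`` in extent.
    """
    ids_s = [m.subject_id for m in maps_sated]
    ids_a = [m.subject_id for m in maps_abstinent]
    if ids_s != ids_a:
        raise ValueError("paired contrast requires the same subjects in the "
                         "same order in both states")
    n = len(maps_sated)
    if n < 3:
        raise ValueError("paired contrast requires at least 3 subjects")
    grid = maps_sated[0].grid
    D = (np.stack([m.values for m in maps_abstinent])
         - np.stack([m.values for m in maps_sated]))      # (n, V)
    sd = D.std(axis=0, ddof=1)
    zero_var = sd == 0
    if np.any(zero_var):
        logger.warning("paired t: skipping %d voxel(s) with zero within-pair "
                       "variance", int(zero_var.sum()))
    t = np.full(grid.n_voxels, np.nan)
    ok = ~zero_var
    t[ok] = D.mean(axis=0)[ok] / (sd[ok] / np.sqrt(n))
    p = np.full_like(t, np.nan)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    supra = ok & (p < voxel_p)

    vol = grid.embed(supra, background=0.0) > 0
    labels, n_lab = ndimage.label(vol,
                                  structure=connectivity_structure(connectivity))
    label_per_voxel = labels[tuple(grid.mask_indices.T)]
    rows, sig = [], np.zeros(grid.n_voxels, dtype=bool)
    cluster_id = 0
    metric = maps_sated[0].metric
    for lab in range(1, n_lab + 1):
        members = np.flatnonzero(label_per_voxel == lab)
        if members.size <= k_threshold:
            continue
        cluster_id += 1
        sig[members] = True
        tv = t[members]
        peak_local = int(np.argmax(np.abs(tv)))
        world = grid.world_coords(grid.mask_indices[members[peak_local]])[0]
        rows.append({
            "cluster_id": cluster_id, "metric": metric,
            "comparison": "abstinent_vs_sated", "size_k": members.size,
            "peak_value": float(tv[peak_local]), "peak_x_mm": world[0],
            "peak_y_mm": world[1], "peak_z_mm": world[2],
        })
    return pd.DataFrame(rows, columns=list(CLUSTER_COLUMNS)), t, sig


# ---------------------------------------------------------------------------
# overlap and rank tests
# ---------------------------------------------------------------------------

def overlap_fraction(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """100 * |A intersect B| / |A| — deliberately asymmetric."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    n_a = a.sum()
    if n_a == 0:
        raise ValueError("overlap undefined: reference mask A is empty")
    return 100.0 * float((a & b).sum()) / float(n_a)


def build_rank_difference_null(normative_zmaps: list[ZScoreMap],
                               voxels: np.ndarray | int, n_a: int, n_b: int,
                               n_perm: int, seed: int) -> np.ndarray:
    """(n_perm, T) per-target |rank difference| null samples.

    ``voxels`` selects the profile: one in-mask voxel index or a set whose
    mean fingerprint is used (for cluster-level profiles).  Each permutation
    splits the normative pool into pseudo-groups, ranks the two mean
    profiles, and records the per-target absolute rank differences.
    """
    Z = np.stack([m.values for m in normative_zmaps])      # (S, V, T)
    sel = np.atleast_1d(np.asarray(voxels, dtype=int))
    profiles = Z[:, sel, :].mean(axis=1)                   # (S, T)
    splits = permutation_splits(Z.shape[0], n_a, n_b, n_perm, seed)
    out = np.empty((n_perm, Z.shape[2]), dtype=int)
    for i, (ia, ib) in enumerate(splits):
        ra = rank_vector(profiles[ia].mean(axis=0))
        rb = rank_vector(profiles[ib].mean(axis=0))
        out[i] = np.abs(ra - rb)
    return out


def target_rank_difference_test(
    rank_a: np.ndarray,
    rank_b: np.ndarray,
    null_rank_diffs: np.ndarray,
    min_diff: int = DEFAULT_MIN_RANK_DIFF,
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Per-target significance of rank differences between two groups.

    A target is flagged when |rank_a - rank_b| is strictly greater than
    ``min_diff`` and at least the (1 - alpha) quantile of its null
    |rank difference| samples.  The signed difference (rank_a - rank_b;
    positive = higher rank, i.e. stronger relative connectivity, in group
    A) is reported for every target.
    """
    ra = np.asarray(rank_a, dtype=int)
    rb = np.asarray(rank_b, dtype=int)
    if ra.shape != rb.shape:
        raise ValueError("rank vectors differ in length")
    null = np.asarray(null_rank_diffs)
    if null.ndim != 2 or null.shape[1] != ra.size:
        raise ValueError("null must be (n_samples, T) aligned to the targets")
    delta = ra - rb
    q = np.quantile(null, 1.0 - alpha, axis=0)
    flagged = (np.abs(delta) > min_diff) & (np.abs(delta) >= q)
    return pd.DataFrame({
        "target": np.arange(ra.size), "rank_a": ra, "rank_b": rb,
        "rank_difference": delta, "null_quantile": q, "significant": flagged,
    })


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------

def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    table = np.asarray(table, dtype=float)
    res = stats.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq == 0):
        raise ValueError("zero expected cell count")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def demographic_balance(records: list[SubjectRecord]) -> pd.DataFrame:
    """Group-balance statistics over unique subjects.

    Two-sample t (equal variance) for age and education; Pearson chi-square
    without continuity correction for sex.  Degrees of freedom reported.
    """
    seen: dict[str, SubjectRecord] = {}
    for r in records:
        seen.setdefault(r.subject_id, r)
    subjects = list(seen.values())
    groups = sorted({r.group for r in subjects})
    if len(groups) != 2:
        raise ValueError("demographic balance requires exactly two groups")
    g0 = [r for r in subjects if r.group == groups[0]]
    g1 = [r for r in subjects if r.group == groups[1]]
    if min(len(g0), len(g1)) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for var in ("age", "education"):
        x = np.array([getattr(r, var) for r in g0], dtype=float)
        y = np.array([getattr(r, var) for r in g1], dtype=float)
        t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append({"variable": var, "test": "t", "statistic": float(t),
                     "df": len(x) + len(y) - 2, "p": float(p)})
    table = np.array([
        [sum(r.sex == "male" for r in g0), sum(r.sex == "female" for r in g0)],
        [sum(r.sex == "male" for r in g1), sum(r.sex == "female" for r in g1)],
    ])
    chi2, dof, p = chi_square_independence(table)
    rows.append({"variable": "sex", "test": "chi2", "statistic": chi2,
                 "df": dof, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fingerprint export
# ---------------------------------------------------------------------------

def fingerprint_polar_export(fingerprints: dict[str, np.ndarray],
                             plot_path: str, csv_path: str,
                             target_names: list[str] | None = None) -> None:
    """Radar-style plot of one or more group fingerprints + exact CSV.

    Spokes follow the fixed target order; the distance of each point from
    the centre is the Fisher-Z connectivity strength.  The CSV round-trips
    the plotted values exactly (one column per target, one row per group).
    """
    if not fingerprints:
        raise ValueError("at least one fingerprint required")
    lengths = {len(v) for v in fingerprints.values()}
    if len(lengths) != 1:
        raise ValueError("fingerprints differ in length")
    T = lengths.pop()
    names = target_names or [f"target_{i}" for i in range(T)]

    df = pd.DataFrame({name: np.asarray(v, dtype=float)
                       for name, v in fingerprints.items()},
                      index=names).T
    df.index.name = "group"
    df.to_csv(csv_path)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    angles = np.linspace(0, 2 * np.pi, T, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for label, values in fingerprints.items():
        v = np.asarray(values, dtype=float)
        ax.plot(np.r_[angles, angles[:1]], np.r_[v, v[:1]], label=label)
    ax.set_xticks(angles)
    ax.set_xticklabels(names, fontsize=7)
    ax.set_title("Connectivity fingerprint (Fisher Z)")
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.savefig(plot_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
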