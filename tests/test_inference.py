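"""Clustering, contrasts, overlap, rank tests, demographics, exports."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpa import inference, metrics
from cpa.connectivity import ZScoreMap
from cpa.io import SubjectRecord, VoxelGrid
from cpa.metrics import MetricMap, rank_vector


def _mmap(values, grid, metric="aggregate_divergence"):
    return MetricMap(metric=metric, values=np.asarray(values, dtype=float),
                     comparison=("A", "B"), grid=grid)


# ---------------------------------------------------------------------------
# threshold_and_cluster
# ---------------------------------------------------------------------------

def test_cluster_all_zero_map_is_empty(small_grid):
    table, mask = inference.threshold_and_cluster(
        _mmap(np.zeros(small_grid.n_voxels), small_grid), 0.5, 7)
    assert len(table) == 0 and not mask.any()


def test_cluster_planted_block_survives_extent(small_grid):
    values = np.zeros(small_grid.n_voxels)
    values[:9] = 2.0   # 9 lexicographically first voxels: a 3x3 y-z sheet
    table, mask = inference.threshold_and_cluster(
        _mmap(values, small_grid), 1.0, 7)
    assert len(table) == 1
    assert table.loc[0, "size_k"] == 9
    assert mask.sum() == 9
    # strict extent rule: k_threshold equal to the size removes the cluster
    table2, _ = inference.threshold_and_cluster(
        _mmap(values, small_grid), 1.0, 9)
    assert len(table2) == 0


def test_cluster_connectivity_rules(small_grid):
    # two diagonally touching voxels: (2,2,2) and (3,3,3)
    values = np.zeros(small_grid.n_voxels)
    idx = {tuple(v): i for i, v in enumerate(small_grid.mask_indices)}
    values[idx[(2, 2, 2)]] = 1.0
    values[idx[(3, 3, 3)]] = 1.0
    t6, _ = inference.threshold_and_cluster(_mmap(values, small_grid),
                                            0.5, 0, connectivity=6)
    t26, _ = inference.threshold_and_cluster(_mmap(values, small_grid),
                                             0.5, 0, connectivity=26)
    assert len(t6) == 2
    assert len(t26) == 1


def test_cluster_peak_world_coordinates_and_ties(small_grid):
    values = np.zeros(small_grid.n_voxels)
    values[:4] = 3.0   # tied peak -> lowest lexicographic voxel index wins
    table, _ = inference.threshold_and_cluster(_mmap(values, small_grid),
                                               1.0, 1)
    peak_voxel = small_grid.mask_indices[0]
    expected = small_grid.world_coords(peak_voxel)[0]
    got = table.loc[0, ["peak_x_mm", "peak_y_mm", "peak_z_mm"]].to_numpy()
    np.testing.assert_allclose(got.astype(float), expected)


def test_cluster_invariant_to_input_voxel_order(small_grid, rng):
    values = (rng.random(small_grid.n_voxels) > 0.6).astype(float)
    perm = rng.permutation(small_grid.n_voxels)
    grid2 = VoxelGrid(small_grid.shape, small_grid.affine,
                      small_grid.mask_indices[perm])   # re-sorted internally
    t1, m1 = inference.threshold_and_cluster(_mmap(values, small_grid), 0.5, 1)
    t2, m2 = inference.threshold_and_cluster(_mmap(values, grid2), 0.5, 1)
    pd.testing.assert_frame_equal(t1, t2)
    np.testing.assert_array_equal(m1, m2)


# ---------------------------------------------------------------------------
# subject maps and paired contrast
# ---------------------------------------------------------------------------

def test_subject_metric_map_identity_and_oracle(small_grid, rng):
    T = 6
    z = ZScoreMap("s1", "sated", rng.normal(size=(small_grid.n_voxels, T)),
                  small_grid)
    same = inference.subject_metric_maps(z, z.values, "rank_misarrangement")
    assert same.values.max() == 0
    ref = rng.normal(size=(small_grid.n_voxels, T))
    out = inference.subject_metric_maps(z, ref, "aggregate_divergence")
    loop = np.array([metrics.aggregate_divergence(z.values[v], ref[v])
                     for v in range(small_grid.n_voxels)])
    np.testing.assert_allclose(out.values, loop, atol=1e-12)


def _subject_maps(grid, values_list, state):
    return [inference.SubjectMetricMap(f"s{i}", state,
                                       "aggregate_divergence", v, grid)
            for i, v in enumerate(values_list)]


def test_paired_contrast_identical_conditions_empty(small_grid, rng):
    vals = [rng.random(small_grid.n_voxels) for _ in range(5)]
    sated = _subject_maps(small_grid, vals, "sated")
    abst = _subject_maps(small_grid, [v.copy() for v in vals], "abstinent")
    table, t, mask = inference.paired_state_contrast(sated, abst)
    assert len(table) == 0 and not mask.any()


def test_paired_contrast_zero_variance_voxel_skipped(small_grid, rng, caplog):
    vals = [0.5 + rng.random(small_grid.n_voxels) for _ in range(5)]
    sated = _subject_maps(small_grid, vals, "sated")
    shifted = [np.abs(v + rng.normal(0, 0.05, v.shape)) for v in vals]
    for i, v in enumerate(shifted):
        v[0] = vals[i][0] + 0.3   # constant shift, zero within-pair variance
    abst = _subject_maps(small_grid, shifted, "abstinent")
    with caplog.at_level(logging.WARNING, logger="cpa"):
        table, t, mask = inference.paired_state_contrast(sated, abst)
    assert np.isnan(t[0])
    assert "zero within-pair" in caplog.text


def test_paired_t_matches_closed_form(small_grid, rng):
    n = 5
    vals = [2.0 + rng.random(small_grid.n_voxels) for _ in range(n)]
    sated = _subject_maps(small_grid, vals, "sated")
    abst = _subject_maps(small_grid,
                         [v + rng.normal(0, 0.2, v.shape) for v in vals],
                         "abstinent")
    _, t, _ = inference.paired_state_contrast(sated, abst)
    diffs = np.stack([a.values - s.values for a, s in zip(abst, sated)])
    v = 7
    expected = diffs[:, v].mean() / (diffs[:, v].std(ddof=1) / np.sqrt(n))
    assert t[v] == pytest.approx(expected, abs=1e-12)
    # algebraic identity with a one-sample t on the differences
    t_scipy = stats.ttest_1samp(diffs[:, v], 0.0).statistic
    assert t[v] == pytest.approx(t_scipy, abs=1e-12)


def test_paired_contrast_requires_matched_subjects(small_grid, rng):
    vals = [rng.random(small_grid.n_voxels) for _ in range(3)]
    sated = _subject_maps(small_grid, vals, "sated")
    abst = _subject_maps(small_grid, vals[::-1], "abstinent")
    abst[0].subject_id = "other"
    with pytest.raises(ValueError, match="same subjects"):
        inference.paired_state_contrast(sated, abst)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def test_overlap_fraction_cases():
    a = np.zeros(10, dtype=bool)
    a[:4] = True
    assert inference.overlap_fraction(a, a) == 100.0
    b = np.zeros(10, dtype=bool)
    b[4:] = True
    assert inference.overlap_fraction(a, b) == 0.0
    b = np.zeros(10, dtype=bool)
    b[2:5] = True   # A = {0..3}, B = {2,3,4} -> |A&B|/|A| = 2/4
    assert inference.overlap_fraction(a, b) == 50.0
    with pytest.raises(ValueError, match="empty"):
        inference.overlap_fraction(np.zeros(5, dtype=bool), b[:5])


def test_overlap_matches_set_oracle(rng):
    for _ in range(20):
        a = rng.random(50) > 0.5
        b = rng.random(50) > 0.5
        if not a.any():
            continue
        sa = set(np.flatnonzero(a).tolist())
        sb = set(np.flatnonzero(b).tolist())
        assert inference.overlap_fraction(a, b) == pytest.approx(
            100 * len(sa & sb) / len(sa))


# ---------------------------------------------------------------------------
# per-target rank-difference test
# ---------------------------------------------------------------------------

def test_rank_difference_identical_ranks_no_flags():
    ranks = np.arange(1, 9)
    null = np.zeros((50, 8), dtype=int)
    out = inference.target_rank_difference_test(ranks, ranks, null)
    assert not out["significant"].any()


def test_rank_difference_strict_min_diff_boundary():
    T = 12
    ra = np.arange(1, T + 1)
    rb = ra.copy()
    rb[0], rb[6] = ra[6], ra[0]    # |diff| 6 at targets 0 and 6
    ra2, rb2 = ra.copy(), ra.copy()
    rb2[0], rb2[5] = ra[5], ra[0]  # |diff| exactly 5 at targets 0 and 5
    permissive = np.zeros((100, T), dtype=int)
    out6 = inference.target_rank_difference_test(ra, rb, permissive)
    assert out6.loc[0, "significant"] and out6.loc[6, "significant"]
    out5 = inference.target_rank_difference_test(ra2, rb2, permissive)
    assert not out5["significant"].any()   # strictly > 5 required


def test_rank_difference_null_from_exhaustive_splits(small_grid):
    """4-subject toy pool, all 2+2 splits enumerated by brute force."""
    rng = np.random.default_rng(3)
    T, voxel = 8, 0
    maps = [ZScoreMap(f"s{i}", "single",
                      rng.normal(size=(small_grid.n_voxels, T)), small_grid)
            for i in range(4)]
    profiles = np.stack([m.values[voxel] for m in maps])

    null_rows = []
    for a_idx in itertools.combinations(range(4), 2):
        b_idx = tuple(sorted(set(range(4)) - set(a_idx)))
        ra = rank_vector(profiles[list(a_idx)].mean(0))
        rb = rank_vector(profiles[list(b_idx)].mean(0))
        null_rows.append(np.abs(ra - rb))
    null = np.stack(null_rows)

    ra = rank_vector(profiles[:2].mean(0))
    rb = rank_vector(profiles[2:].mean(0))
    out = inference.target_rank_difference_test(ra, rb, null, min_diff=2,
                                                alpha=0.2)
    # brute-force recomputation of the rule
    delta = ra - rb
    q = np.quantile(null, 0.8, axis=0)
    expected = (np.abs(delta) > 2) & (np.abs(delta) >= q)
    np.testing.assert_array_equal(out["significant"].to_numpy(), expected)
    np.testing.assert_array_equal(out["rank_difference"].to_numpy(), delta)


def test_build_rank_difference_null_shapes(small_grid, rng):
    maps = [ZScoreMap(f"s{i}", "single",
                      rng.normal(size=(small_grid.n_voxels, 6)), small_grid)
            for i in range(6)]
    null = inference.build_rank_difference_null(maps, voxels=0, n_a=3, n_b=3,
                                                n_perm=40, seed=0)
    assert null.shape == (40, 6)
    assert null.min() >= 0 and null.max() <= 5


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------

def test_chi_square_reproduces_reported_group_balance():
    # sex counts by group: 27/19 male/female vs 21/12
    chi2, dof, p = inference.chi_square_independence([[27, 19], [21, 12]])
    assert dof == 1
    assert chi2 == pytest.approx(0.197, abs=0.005)
    # scanner counts by group: 26/7 vs 31/15
    chi2, dof, _ = inference.chi_square_independence([[26, 7], [31, 15]])
    assert chi2 == pytest.approx(1.24, abs=0.005)


def test_demographic_balance_identical_groups():
    records = []
    for g, prefix in (("smoker", "s"), ("nonsmoker", "c")):
        state = "sated" if g == "smoker" else "single"
        for i, (age, sex, edu) in enumerate(
                [(30, "male", 12), (40, "female", 14), (50, "male", 16)]):
            records.append(SubjectRecord(f"{prefix}{i}", g, state, age, sex,
                                         edu))
    out = inference.demographic_balance(records)
    assert set(out["variable"]) == {"age", "education", "sex"}
    assert np.allclose(out[out["test"] == "t"]["statistic"], 0.0)
    assert out[out["variable"] == "sex"]["statistic"].iloc[0] == \
        pytest.approx(0.0)
    assert (out[out["test"] == "t"]["df"] == 4).all()


# ---------------------------------------------------------------------------
# polar export
# ---------------------------------------------------------------------------

def test_polar_export_round_trips_values(tmp_path, rng):
    fps = {"nonsmoker": rng.normal(size=8),
           "smoker_sated": rng.normal(size=8),
           "smoker_abstinent": rng.normal(size=8)}
    names = [f"roi_{i}" for i in range(8)]
    png = tmp_path / "polar.png"
    csv = tmp_path / "polar.csv"
    inference.fingerprint_polar_export(fps, str(png), str(csv),
                                       target_names=names)
    assert png.exists() and png.stat().st_size > 0
    back = pd.read_csv(csv, index_col=0, float_precision="round_trip")
    assert list(back.columns) == names          # spoke order = target order
    assert list(back.index) == list(fps)        # three overlaid series
    for k in fps:
        np.testing.assert_array_equal(back.loc[k].to_numpy(), fps[k])
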