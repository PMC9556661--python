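"""Cluster-mean extraction and covariate-adjusted OLS against explicit
normal-equations oracles."""

import numpy as np
import pytest

from cpa import behavior
from cpa.inference import SubjectMetricMap


def _design(frame_cols):
    return np.column_stack([np.ones(len(frame_cols[0]))] + frame_cols)


def ols_oracle(y, cols):
    """Coefficients, standard errors and t statistics by explicit solve."""
    X = _design(cols)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return beta, se, beta / se


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_extract_cluster_means(small_grid, rng):
    maps = [SubjectMetricMap(f"s{i}", "abstinent", "aggregate_divergence",
                             rng.random(small_grid.n_voxels), small_grid)
            for i in range(4)]
    mask = np.zeros(small_grid.n_voxels, dtype=bool)
    mask[5] = True
    np.testing.assert_allclose(
        behavior.extract_cluster_means(maps, mask),
        [m.values[5] for m in maps])
    constant = SubjectMetricMap("c", "abstinent", "entropy_shift",
                                np.full(small_grid.n_voxels, 0.7), small_grid)
    mask[10:14] = True
    assert behavior.extract_cluster_means([constant], mask)[0] == \
        pytest.approx(0.7)
    rand_mask = rng.random(small_grid.n_voxels) > 0.5
    got = behavior.extract_cluster_means(maps, rand_mask)
    np.testing.assert_allclose(
        got, [m.values[rand_mask].mean() for m in maps])
    with pytest.raises(ValueError, match="empty"):
        behavior.extract_cluster_means(maps, np.zeros_like(mask))


# ---------------------------------------------------------------------------
# interaction regression
# ---------------------------------------------------------------------------

def _covariates(rng, n):
    return (rng.uniform(20, 55, n), rng.integers(0, 2, n).astype(float),
            rng.uniform(10, 18, n))


def test_interaction_exact_fit_recovered_to_machine_precision(rng):
    n = 30
    ad, rom = rng.normal(2, 0.5, n), rng.normal(100, 20, n)
    age, sex, edu = _covariates(rng, n)
    ad_c, rom_c = ad - ad.mean(), rom - rom.mean()
    outcome = 4.0 + 2.5 * ad_c * rom_c   # pure interaction, zero noise
    res = behavior.interaction_regression(outcome, ad, rom, age, sex, edu)
    assert res.term("ad_x_rom")["coef"] == pytest.approx(2.5, abs=1e-10)
    # all other slopes vanish
    for term in ("ad", "rom", "age", "sex", "education"):
        assert abs(res.term(term)["coef"]) < 1e-9


def test_interaction_matches_normal_equations_oracle(rng):
    for _ in range(20):
        n = 20
        ad, rom = rng.normal(size=n), rng.normal(size=n)
        age, sex, edu = _covariates(rng, n)
        y = rng.normal(size=n)
        res = behavior.interaction_regression(y, ad, rom, age, sex, edu)
        ad_c, rom_c = ad - ad.mean(), rom - rom.mean()
        beta, se, t = ols_oracle(y, [ad_c, rom_c, ad_c * rom_c, age, sex,
                                     edu])
        got = res.table.set_index("term")
        order = ["const", "ad", "rom", "ad_x_rom", "age", "sex", "education"]
        np.testing.assert_allclose(got.loc[order, "coef"], beta, atol=1e-8)
        np.testing.assert_allclose(got.loc[order, "t"], t, atol=1e-8)
        assert res.residual_df == n - 7


def test_interaction_t_invariant_to_centering_and_rescaling(rng):
    n = 25
    ad, rom = rng.normal(3, 1, n), rng.normal(50, 10, n)
    age, sex, edu = _covariates(rng, n)
    y = rng.normal(size=n) + 0.02 * ad * rom
    res = behavior.interaction_regression(y, ad, rom, age, sex, edu)
    # highest-order term's t is unchanged by NOT centering (fit manually)
    beta, se, t = ols_oracle(y, [ad, rom, ad * rom, age, sex, edu])
    assert res.term("ad_x_rom")["t"] == pytest.approx(t[3], abs=1e-8)
    # affine rescaling of covariates leaves all t statistics unchanged
    res2 = behavior.interaction_regression(y, ad, rom, age / 10 + 3, sex,
                                           edu * 2 - 5)
    # slope t statistics are invariant to affine covariate rescaling (the
    # intercept's meaning changes, so it is excluded)
    np.testing.assert_allclose(res.table["t"][1:], res2.table["t"][1:],
                               atol=1e-8)


def test_permuted_outcome_interaction_t_centred_on_zero(rng):
    n = 24
    ad, rom = rng.normal(size=n), rng.normal(size=n)
    age, sex, edu = _covariates(rng, n)
    y = rng.normal(size=n)
    ts = []
    for _ in range(200):
        res = behavior.interaction_regression(rng.permutation(y), ad, rom,
                                              age, sex, edu)
        ts.append(res.term("ad_x_rom")["t"])
    assert abs(np.mean(ts)) < 0.25
    assert np.mean(np.abs(ts)) < 2.0


def test_collinear_design_raises_with_term_names(rng):
    n = 20
    ad = rng.normal(size=n)
    age, sex, edu = _covariates(rng, n)
    with pytest.raises(ValueError, match="collinear"):
        behavior.interaction_regression(rng.normal(size=n), ad, 2 * ad, age,
                                        sex, edu)


def test_listwise_deletion_of_missing_values(rng):
    n = 15
    ad, rom = rng.normal(size=n), rng.normal(size=n)
    age, sex, edu = _covariates(rng, n)
    y = rng.normal(size=n)
    y_missing = y.copy()
    y_missing[3] = np.nan
    res = behavior.interaction_regression(y_missing, ad, rom, age, sex, edu)
    keep = np.arange(n) != 3
    ref = behavior.interaction_regression(y[keep], ad[keep], rom[keep],
                                          age[keep], sex[keep], edu[keep])
    assert res.n_used == n - 1
    np.testing.assert_allclose(res.table["coef"], ref.table["coef"],
                               atol=1e-12)


# ---------------------------------------------------------------------------
# withdrawal regression
# ---------------------------------------------------------------------------

def test_withdrawal_regression_zero_variance_predictor(rng):
    n = 12
    age, sex, edu = _covariates(rng, n)
    with pytest.raises(ValueError, match="collinear"):
        behavior.withdrawal_regression(rng.normal(size=n), np.full(n, 1.3),
                                       age, sex, edu)


def test_withdrawal_regression_oracle_and_sign(rng):
    n = 30
    predictor = rng.normal(2, 0.6, n)
    age, sex, edu = _covariates(rng, n)
    y = 5 + 1.8 * predictor + rng.normal(0, 0.5, n)
    res = behavior.withdrawal_regression(y, predictor, age, sex, edu)
    beta, se, t = ols_oracle(y, [predictor, age, sex, edu])
    got = res.table.set_index("term")
    order = ["const", "predictor", "age", "sex", "education"]
    np.testing.assert_allclose(got.loc[order, "coef"], beta, atol=1e-8)
    assert res.term("predictor")["coef"] > 0


def test_residuals_orthogonal_to_design(rng):
    n = 40
    ad, rom = rng.normal(size=n), rng.normal(size=n)
    age, sex, edu = _covariates(rng, n)
    y = rng.normal(size=n)
    res = behavior.interaction_regression(y, ad, rom, age, sex, edu)
    ad_c, rom_c = ad - ad.mean(), rom - rom.mean()
    X = _design([ad_c, rom_c, ad_c * rom_c, age, sex, edu])
    coefs = res.table.set_index("term").loc[
        ["const", "ad", "rom", "ad_x_rom", "age", "sex", "education"],
        "coef"].to_numpy()
    resid = y - X @ coefs
    assert np.abs(X.T @ resid).max() < 1e-8


def test_planted_withdrawal_association_sign_recovered(tmp_path):
    """Smokers' withdrawal scores are generated to rise with the same
    severity modulator that scales their planted effect, so regressing
    withdrawal on the subject-level misconfiguration magnitude over the
    planted region must recover a positive coefficient.  The
    concentration effect is used because its magnitude responds linearly
    to the severity modulator (the gain effect saturates in r)."""
    import pandas as pd
    from cpa import io as cio
    from cpa.inference import subject_metric_maps
    from cpa.pipeline import AnalysisConfig, run_pipeline, load_zmaps
    from cpa.synthdata import PlantedRegion, ScenarioConfig, generate_dataset

    root = tmp_path / "assoc"
    cfg = ScenarioConfig(
        n_smokers=20, n_nonsmokers=8, n_normative=0,
        n_high_motion_smokers=0, n_high_motion_nonsmokers=0,
        shape=(10, 10, 10), mask_center=(4.5, 4.5, 4.5), mask_radius=2.8,
        n_targets=12, n_frames=240, ladder_step=0.037,
        severity_modulation=(0.0, 2.0),
        planted=[PlantedRegion((4.5, 4.5, 4.5), 2.8, "concentration", 1.0,
                               "abstinent_only")],
        seed=21)
    _, _, truth = generate_dataset(cfg, root)
    ac = AnalysisConfig(
        bold_dir=str(root / "bold"), confounds_dir=str(root / "confounds"),
        striatal_mask=str(root / "striatal_mask.nii"),
        targets=str(root / "targets.nii"),
        manifest=str(root / "manifest.csv"),
        normative_manifest=str(root / "normative_manifest.csv"),
        output_dir=str(root / "analysis"), n_targets=12, seed=3)
    run_pipeline(ac, stages=["fingerprints"])
    zmaps, labels = load_zmaps(ac, "empirical", "t")

    reference = np.mean([z.values for z, lab in zip(zmaps, labels)
                         if lab == "nonsmoker"], axis=0)
    abst = [z for z, lab in zip(zmaps, labels)
            if lab == "smoker_abstinent"]
    maps = [subject_metric_maps(z, reference, "entropy_shift")
            for z in abst]
    region = np.zeros(truth.labels.size, dtype=bool)
    region[truth.region_voxels["concentration"]] = True
    es_mag = behavior.extract_cluster_means(maps, region)

    records = {r.subject_id: r
               for r in cio.read_manifest(root / "manifest.csv")
               if r.state == "abstinent"}
    sids = [m.subject_id for m in maps]
    withdrawal = np.array([records[s].withdrawal for s in sids])
    age = np.array([records[s].age for s in sids])
    sex = np.array([records[s].sex for s in sids])
    edu = np.array([records[s].education for s in sids])

    # the generative severity drives both quantities
    sev = np.array([truth.severities[s] for s in sids])
    assert np.corrcoef(sev, es_mag)[0, 1] > 0.3

    res = behavior.withdrawal_regression(withdrawal, es_mag, age, sex, edu)
    assert res.term("predictor")["coef"] > 0
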