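"""End-to-end orchestration: config, staged execution, persisted artifacts.

Stages (each idempotent and resumable from persisted intermediates):

``fingerprints``  BOLD + confounds -> per-session voxel-by-target Fisher-Z
                  maps with censoring, exclusion, nuisance GLM and group
                  FD adjustment.
``null``          normative permutation nulls: per-metric voxel thresholds
                  and cluster-extent thresholds.
``groupmaps``     group-average fingerprints and empirical metric maps for
                  the sated and abstinent group comparisons.
``clusters``      thresholding + cluster-extent filtering, cluster tables,
                  significance masks, overlap statistics.
``within``        subject-level metric maps and the paired state contrast.
``behavior``      cluster-mean misconfiguration magnitudes vs severity
                  scores (interaction and withdrawal regressions).
``report``        fingerprint polar plot at the peak voxel + run summary.

A stage that needs missing intermediates raises an error naming the stage
to run first.  All randomness flows from the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import inference, metrics, nullmodel
from . import behavior as behav
from . import io as cio
from .io import SubjectRecord, VoxelGrid

logger = logging.getLogger("cpa")

STAGES = ("fingerprints", "null", "groupmaps", "clusters", "within",
          "behavior", "report")

COMPARISONS = (("smoker_abstinent", "nonsmoker"),
               ("smoker_sated", "nonsmoker"))


class MissingStageError(RuntimeError):
    def __init__(self, needed: str, stage: str):
        super().__init__(
            f"stage '{stage}' needs intermediates produced by stage "
            f"'{needed}'; run '{needed}' first")


@dataclass
class AnalysisConfig:
    """All pipeline settings; fully serialised into every output directory."""

    bold_dir: str = "bold"
    confounds_dir: str = "confounds"
    striatal_mask: str = "striatal_mask.nii"
    targets: str = "targets.nii"
    manifest: str = "manifest.csv"
    normative_manifest: str = "normative_manifest.csv"
    output_dir: str = "cpa_out"
    n_targets: int = 30
    fd_threshold: float = 0.5
    n_leading: int = 3
    max_censored_fraction: float = 0.25
    poly_order: int = 2
    alpha: float = 1e-3
    alpha_fwe: float = 0.05
    n_perm: int = 1000
    connectivity: int = 6
    min_rank_diff: int = 5
    entropy_base: float | None = None   # None = natural log
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.alpha_fwe < 1:
            raise ValueError("alpha levels must be in (0, 1)")
        for name in ("fd_threshold", "n_leading", "max_censored_fraction",
                     "n_perm", "min_rank_diff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def out(self) -> Path:
        return Path(self.output_dir)


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def _session_key(rec: SubjectRecord) -> str:
    return f"{rec.subject_id}_{rec.state}"


def _load_grid(config: AnalysisConfig) -> VoxelGrid:
    return cio.read_mask(config.striatal_mask)


def compute_session_zmap(config: AnalysisConfig, rec: SubjectRecord,
                         grid: VoxelGrid, targets: list[np.ndarray]
                         ) -> tuple[conn.ZScoreMap | None, float, float]:
    """One session's Z map (or None if motion-excluded), mean FD and the
    censored fraction."""
    bold_path = Path(config.bold_dir) / f"{_session_key(rec)}_bold.nii"
    conf_path = (Path(config.confounds_dir)
                 / f"{_session_key(rec)}_confounds.tsv")
    data, bold_grid = cio.read_bold(bold_path)
    if bold_grid.shape != grid.shape:
        raise cio.FormatError(f"{bold_path}: grid mismatch with striatal mask")
    confounds = cio.read_confounds(conf_path)
    if confounds.n_frames != data.shape[3]:
        raise cio.FormatError(f"{conf_path}: frame count mismatch")

    mask = conn.censor_frames(confounds.fd, config.fd_threshold,
                              config.n_leading)
    mean_fd = float(confounds.fd.mean())
    if not conn.check_exclusion(mask, config.max_censored_fraction):
        logger.warning("excluding %s: %.1f%% frames censored",
                       _session_key(rec), 100 * mask.fraction_censored)
        return None, mean_fd, mask.fraction_censored

    nuisance = conn.build_nuisance(confounds, keep=mask,
                                   poly_order=config.poly_order)
    voxel_ts = grid.extract(data)                        # (V, F)
    target_ts = np.stack([data[tuple(t.T)].mean(axis=0) for t in targets])
    r = conn.fingerprint_matrix(voxel_ts, target_ts, nuisance=nuisance,
                                keep=mask)
    z = conn.fisher_z(r)
    zmap = conn.ZScoreMap(subject_id=rec.subject_id, state=rec.state,
                          values=z, grid=grid)
    return zmap, mean_fd, mask.fraction_censored


def stage_fingerprints(config: AnalysisConfig) -> None:
    grid = _load_grid(config)
    targets = cio.read_targets(config.targets, config.n_targets)
    fp_dir = config.out / "fingerprints"
    fp_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for kind, manifest in (("empirical", config.manifest),
                           ("normative", config.normative_manifest)):
        records = cio.read_manifest(manifest)
        zmaps, fds, kept = [], [], []
        for rec in records:
            zmap, mean_fd, frac = compute_session_zmap(config, rec, grid,
                                                       targets)
            rows.append({"session": _session_key(rec), "set": kind,
                         "group": rec.group, "state": rec.state,
                         "mean_fd": mean_fd, "censored_fraction": frac,
                         "included": zmap is not None})
            if zmap is not None:
                zmaps.append(zmap)
                fds.append(mean_fd)
                kept.append(rec)
        if len(zmaps) >= 3:
            adjusted = conn.fd_adjust(zmaps, np.array(fds))
        else:
            if zmaps:
                logger.warning("too few %s sessions for FD adjustment", kind)
            adjusted = zmaps
        for rec, zmap in zip(kept, adjusted):
            np.savez(fp_dir / f"{kind}_{_session_key(rec)}.npz",
                     values=zmap.values, subject_id=rec.subject_id,
                     state=rec.state, group=rec.group,
                     grid_checksum=grid.index_checksum())
    pd.DataFrame(rows).to_csv(config.out / "sessions.csv", index=False)
    config.to_yaml(config.out / "config_used.yaml")
    logger.info("fingerprints: %d sessions processed", len(rows))


def load_zmaps(config: AnalysisConfig, kind: str, stage: str
               ) -> tuple[list[conn.ZScoreMap], list[str]]:
    """Load persisted (FD-adjusted) Z maps of one set; returns maps +
    group labels ('smoker_sated', 'smoker_abstinent', 'nonsmoker')."""
    grid = _load_grid(config)
    fp_dir = config.out / "fingerprints"
    paths = sorted(fp_dir.glob(f"{kind}_*.npz"))
    if not paths:
        raise MissingStageError("fingerprints", stage)
    zmaps, labels = [], []
    for p in paths:
        d = np.load(p, allow_pickle=False)
        if int(d["grid_checksum"]) != grid.index_checksum():
            raise ValueError(f"{p}: voxel ordering does not match the "
                             "striatal mask grid")
        group, state = str(d["group"]), str(d["state"])
        zmaps.append(conn.ZScoreMap(subject_id=str(d["subject_id"]),
                                    state=state, values=d["values"],
                                    grid=grid))
        labels.append(group if group == "nonsmoker" else f"smoker_{state}")
    return zmaps, labels


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def _group_sizes(config: AnalysisConfig, stage: str) -> tuple[int, int]:
    sessions = config.out / "sessions.csv"
    if not sessions.exists():
        raise MissingStageError("fingerprints", stage)
    df = pd.read_csv(sessions)
    emp = df[(df["set"] == "empirical") & df["included"]]
    n_a = int(((emp["group"] == "smoker")
               & (emp["state"] == "abstinent")).sum())
    n_b = int((emp["group"] == "nonsmoker").sum())
    return n_a, n_b


def stage_null(config: AnalysisConfig) -> None:
    zmaps, _ = load_zmaps(config, "normative", "null")
    n_a, n_b = _group_sizes(config, "null")
    null_dir = config.out / "null"
    null_dir.mkdir(parents=True, exist_ok=True)
    thresholds = {}
    for i, metric in enumerate(metrics.METRICS):
        null = nullmodel.build_null(
            zmaps, metric, n_a, n_b, n_perm=config.n_perm,
            alpha=config.alpha, seed=config.seed + i,
            entropy_base=config.entropy_base)
        cnull = nullmodel.cluster_size_null(
            zmaps, metric, null.threshold, n_a, n_b, n_perm=config.n_perm,
            alpha_fwe=config.alpha_fwe, connectivity=config.connectivity,
            seed=config.seed + 100 + i, entropy_base=config.entropy_base)
        null.save(null_dir / f"{metric}_null.csv",
                  null_dir / f"{metric}_null.json")
        thresholds[metric] = {
            "voxel_threshold": null.threshold,
            # clusters must reach k_threshold voxels; the strict "k >"
            # rule therefore uses k_threshold - 1
            "k_threshold": int(cnull.k_threshold),
            "n_permutations": config.n_perm,
            "group_sizes": [n_a, n_b],
        }
    (null_dir / "thresholds.json").write_text(json.dumps(thresholds,
                                                         indent=2))
    logger.info("null: thresholds %s",
                {m: round(v["voxel_threshold"], 4)
                 for m, v in thresholds.items()})


def load_thresholds(config: AnalysisConfig, stage: str) -> dict:
    path = config.out / "null" / "thresholds.json"
    if not path.exists():
        raise MissingStageError("null", stage)
    return json.loads(path.read_text())


# ---------------------------------------------------------------------------
# group maps and clusters
# ---------------------------------------------------------------------------

def stage_groupmaps(config: AnalysisConfig) -> None:
    zmaps, labels = load_zmaps(config, "empirical", "groupmaps")
    grid = zmaps[0].grid
    averages = conn.group_average_fingerprints(zmaps, labels)
    gm_dir = config.out / "groupmaps"
    gm_dir.mkdir(parents=True, exist_ok=True)
    np.savez(gm_dir / "group_fingerprints.npz", **averages)
    for ga, gb in COMPARISONS:
        for metric in metrics.METRICS:
            mmap = metrics.metric_map(averages[ga], averages[gb], metric,
                                      grid, comparison=(ga, gb),
                                      entropy_base=config.entropy_base)
            tag = f"{metric}__{ga}_vs_{gb}"
            np.save(gm_dir / f"{tag}.npy", mmap.values)
            cio.write_map(gm_dir / f"{tag}.nii", mmap.values, grid)
    logger.info("groupmaps: %d metric maps written",
                len(COMPARISONS) * len(metrics.METRICS))


def load_metric_map(config: AnalysisConfig, metric: str, ga: str, gb: str,
                    stage: str) -> metrics.MetricMap:
    path = config.out / "groupmaps" / f"{metric}__{ga}_vs_{gb}.npy"
    if not path.exists():
        raise MissingStageError("groupmaps", stage)
    return metrics.MetricMap(metric=metric, values=np.load(path),
                             comparison=(ga, gb), grid=_load_grid(config))


def stage_clusters(config: AnalysisConfig) -> None:
    thresholds = load_thresholds(config, "clusters")
    cl_dir = config.out / "clusters"
    cl_dir.mkdir(parents=True, exist_ok=True)
    tables, masks = [], {}
    for ga, gb in COMPARISONS:
        for metric in metrics.METRICS:
            mmap = load_metric_map(config, metric, ga, gb, "clusters")
            th = thresholds[metric]
            table, sig = inference.threshold_and_cluster(
                mmap, th["voxel_threshold"], th["k_threshold"] - 1,
                config.connectivity)
            tables.append(table)
            masks[(metric, f"{ga}_vs_{gb}")] = sig
            tag = f"{metric}__{ga}_vs_{gb}"
            cio.write_map(cl_dir / f"{tag}_mask.nii", sig.astype(float),
                          mmap.grid)
            np.save(cl_dir / f"{tag}_mask.npy", sig)
    nonempty = [t for t in tables if len(t)] or [tables[0]]
    pd.concat(nonempty, ignore_index=True).to_csv(
        cl_dir / "cluster_table.csv", index=False)

    # overlap statistics: across metrics within comparison, and across
    # states within metric (the trait/state constancy quantity)
    rows = []
    for (m1, c1), a in masks.items():
        for (m2, c2), b in masks.items():
            if (m1, c1) == (m2, c2) or a.sum() == 0:
                continue
            rows.append({"mask_a": f"{m1}|{c1}", "mask_b": f"{m2}|{c2}",
                         "overlap_pct":
                             inference.overlap_fraction(a, b)})
    pd.DataFrame(rows).to_csv(cl_dir / "overlaps.csv", index=False)
    logger.info("clusters: %d surviving clusters",
                sum(len(t) for t in tables))


def load_significance_masks(config: AnalysisConfig, stage: str
                            ) -> dict[tuple[str, str], np.ndarray]:
    cl_dir = config.out / "clusters"
    masks = {}
    for ga, gb in COMPARISONS:
        for metric in metrics.METRICS:
            path = cl_dir / f"{metric}__{ga}_vs_{gb}_mask.npy"
            if not path.exists():
                raise MissingStageError("clusters", stage)
            masks[(metric, f"{ga}_vs_{gb}")] = np.load(path)
    return masks


# ---------------------------------------------------------------------------
# within-smoker contrast
# ---------------------------------------------------------------------------

def _paired_subject_maps(config: AnalysisConfig, metric: str, stage: str
                         ) -> tuple[list, list]:
    zmaps, labels = load_zmaps(config, "empirical", stage)
    averages = conn.group_average_fingerprints(zmaps, labels)
    reference = averages["nonsmoker"]
    by_state: dict[str, dict[str, conn.ZScoreMap]] = {"sated": {},
                                                      "abstinent": {}}
    for z, lab in zip(zmaps, labels):
        if lab.startswith("smoker"):
            by_state[z.state][z.subject_id] = z
    paired_ids = sorted(set(by_state["sated"]) & set(by_state["abstinent"]))
    if len(paired_ids) < 3:
        raise ValueError("fewer than 3 smokers with both sessions")
    sated = [inference.subject_metric_maps(by_state["sated"][sid], reference,
                                           metric,
                                           entropy_base=config.entropy_base)
             for sid in paired_ids]
    abstinent = [inference.subject_metric_maps(by_state["abstinent"][sid],
                                               reference, metric,
                                               entropy_base=config.entropy_base)
                 for sid in paired_ids]
    return sated, abstinent


def stage_within(config: AnalysisConfig) -> None:
    thresholds = load_thresholds(config, "within")
    w_dir = config.out / "within"
    w_dir.mkdir(parents=True, exist_ok=True)
    tables = []
    for metric in metrics.METRICS:
        sated, abstinent = _paired_subject_maps(config, metric, "within")
        table, tmap, sig = inference.paired_state_contrast(
            sated, abstinent, voxel_p=config.alpha,
            k_threshold=thresholds[metric]["k_threshold"] - 1,
            connectivity=config.connectivity)
        tables.append(table)
        grid = sated[0].grid
        cio.write_map(w_dir / f"{metric}_tmap.nii",
                      np.nan_to_num(tmap), grid)
        np.save(w_dir / f"{metric}_mask.npy", sig)
        for maps, tag in ((sated, "sated"), (abstinent, "abstinent")):
            np.savez(w_dir / f"{metric}_subject_maps_{tag}.npz",
                     values=np.stack([m.values for m in maps]),
                     subject_ids=[m.subject_id for m in maps])
    nonempty = [t for t in tables if len(t)] or [tables[0]]
    pd.concat(nonempty, ignore_index=True).to_csv(
        w_dir / "paired_contrast_clusters.csv", index=False)
    logger.info("within: paired contrasts complete")


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def _behavior_mask(config: AnalysisConfig) -> np.ndarray:
    """Cluster over which subject-level magnitudes are extracted: the
    abstinent-comparison AD-and-ROM overlap if it is non-empty, else the
    largest abstinent AD cluster."""
    masks = load_significance_masks(config, "behavior")
    ad = masks[("aggregate_divergence", "smoker_abstinent_vs_nonsmoker")]
    rom = masks[("rank_misarrangement", "smoker_abstinent_vs_nonsmoker")]
    both = ad & rom
    if both.any():
        return both
    if ad.any():
        return ad
    raise ValueError("no significant aggregate-divergence cluster to "
                     "extract behaviour predictors from")


def stage_behavior(config: AnalysisConfig) -> None:
    mask = _behavior_mask(config)
    b_dir = config.out / "behavior"
    b_dir.mkdir(parents=True, exist_ok=True)
    np.save(b_dir / "extraction_mask.npy", mask)

    records = {(_session_key(r)): r for r in cio.read_manifest(config.manifest)}
    ad_sated, ad_abst = _paired_subject_maps(config, "aggregate_divergence",
                                             "behavior")
    rom_sated, rom_abst = _paired_subject_maps(config, "rank_misarrangement",
                                               "behavior")
    sids = [m.subject_id for m in ad_abst]
    ad_mag = behav.extract_cluster_means(ad_abst, mask)
    rom_mag = behav.extract_cluster_means(rom_abst, mask)

    def col(attr):
        return np.array([getattr(records[f"{sid}_abstinent"], attr)
                         if getattr(records[f"{sid}_abstinent"], attr)
                         is not None else np.nan for sid in sids],
                        dtype=object).astype(float)

    sex = np.array([records[f"{sid}_abstinent"].sex for sid in sids])
    ftnd = col("ftnd")
    withdrawal = col("withdrawal")
    age, edu = col("age"), col("education")

    res_int = behav.interaction_regression(ftnd, ad_mag, rom_mag, age, sex,
                                           edu)
    behav.save_regression(
        res_int, b_dir / "ftnd_interaction.csv",
        b_dir / "ftnd_interaction.json",
        spec={"outcome": "ftnd",
              "terms": ["const", "ad", "rom", "ad_x_rom", "age", "sex",
                        "education"]})
    res_wd = behav.withdrawal_regression(withdrawal, ad_mag, age, sex, edu)
    behav.save_regression(
        res_wd, b_dir / "withdrawal_ad.csv", b_dir / "withdrawal_ad.json",
        spec={"outcome": "withdrawal",
              "terms": ["const", "ad", "age", "sex", "education"]})
    pd.DataFrame({"subject_id": sids, "ad_magnitude": ad_mag,
                  "rom_magnitude": rom_mag, "ftnd": ftnd,
                  "withdrawal": withdrawal}).to_csv(
        b_dir / "subject_magnitudes.csv", index=False)
    logger.info("behavior: n=%d smokers in regressions", res_int.n_used)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def stage_report(config: AnalysisConfig) -> None:
    r_dir = config.out / "report"
    r_dir.mkdir(parents=True, exist_ok=True)
    zmaps, labels = load_zmaps(config, "empirical", "report")
    averages = conn.group_average_fingerprints(zmaps, labels)
    mmap = load_metric_map(config, "aggregate_divergence", "smoker_abstinent",
                           "nonsmoker", "report")
    peak = int(np.argmax(mmap.values))
    fingerprints = {g: averages[g][peak] for g in sorted(averages)}
    inference.fingerprint_polar_export(
        fingerprints, str(r_dir / "peak_fingerprints.png"),
        str(r_dir / "peak_fingerprints.csv"))

    # per-target rank differences at the peak rank-misarrangement voxel
    rom_map = load_metric_map(config, "rank_misarrangement",
                              "smoker_sated", "nonsmoker", "report")
    rom_peak = int(np.argmax(rom_map.values))
    zn, _ = load_zmaps(config, "normative", "report")
    null = inference.build_rank_difference_null(
        zn, rom_peak, *_group_sizes(config, "report"),
        n_perm=config.n_perm, seed=config.seed + 500)
    rank_table = inference.target_rank_difference_test(
        metrics.rank_vector(averages["smoker_sated"][rom_peak]),
        metrics.rank_vector(averages["nonsmoker"][rom_peak]),
        null, min_diff=config.min_rank_diff, alpha=config.alpha)
    rank_table.to_csv(r_dir / "peak_rank_differences.csv", index=False)

    summary = {"peak_voxel_index": peak,
               "peak_world_mm": mmap.grid.world_coords(
                   mmap.grid.mask_indices[peak])[0].tolist(),
               "thresholds": load_thresholds(config, "report"),
               "seed": config.seed}
    cluster_csv = config.out / "clusters" / "cluster_table.csv"
    if cluster_csv.exists():
        summary["n_clusters"] = int(len(pd.read_csv(cluster_csv)))
    (r_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("report written to %s", r_dir)


_STAGE_FNS = {
    "fingerprints": stage_fingerprints,
    "null": stage_null,
    "groupmaps": stage_groupmaps,
    "clusters": stage_clusters,
    "within": stage_within,
    "behavior": stage_behavior,
    "report": stage_report,
}


def run_pipeline(config: AnalysisConfig,
                 stages: tuple[str, ...] | list[str] = STAGES) -> None:
    """Run the requested stages in canonical order."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    config.out.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage in stages:
            logger.info("=== stage %s ===", stage)
            _STAGE_FNS[stage](config)


def run_synthetic_demo(root: str | Path, seed: int = 0, n_perm: int = 200,
                       scenario=None,
                       stages: tuple[str, ...] | list[str] = STAGES):
    """Generate the default synthetic scenario under ``root`` and analyse it.

    Returns (AnalysisConfig, GroundTruth).  Convenience entry point used by
    the worked example and the result-reproduction script.
    """
    from .synthdata import ScenarioConfig, generate_dataset

    root = Path(root)
    scenario = scenario if scenario is not None else ScenarioConfig(seed=seed)
    _, _, truth = generate_dataset(scenario, root)
    config = AnalysisConfig(
        bold_dir=str(root / "bold"), confounds_dir=str(root / "confounds"),
        striatal_mask=str(root / "striatal_mask.nii"),
        targets=str(root / "targets.nii"),
        manifest=str(root / "manifest.csv"),
        normative_manifest=str(root / "normative_manifest.csv"),
        output_dir=str(root / "analysis"),
        n_targets=scenario.n_targets, n_perm=n_perm, seed=seed + 1)
    run_pipeline(config, stages=stages)
    return config, truth
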