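"""Fully synthetic multi-subject two-session datasets with planted effects.

The generator emulates the statistical structure the pipeline consumes —
not hemodynamics.  T frontal target ROIs carry band-limited (0.01-0.1 Hz)
latent series that share a common low-frequency component (frontal ROI
series are mutually correlated in real resting-state data).  Each striatal
voxel's series is a noisy linear mixture of those target signals plus a
private signal component and broadband noise, constructed so that the
voxel's *structural* correlations with the T targets follow a fixed
Fisher-Z ladder  z_t = z0 + step * rank  — i.e. every voxel has a
well-ordered connectivity fingerprint.  Per-(session, voxel) gain jitter
(shared across targets) creates realistic aggregate-strength variability
without disturbing rank order; per-cell weight jitter adds independent
fingerprint noise.

Ground-truth misconfigurations are planted in disjoint spherical regions
of the striatal mask, one per effect type:

``gain``             all mixing weights scaled by (1 + effect); raises every
                     connection strength (aggregate-divergence-type).
``rank_permutation`` the central block of ``effect`` consecutive ranks of
                     the weight ladder is reversed (rank-order-type).
``concentration``    the weight ladder is power-transformed with exponent
                     (1 + effect) and rescaled to preserve total
                     weight magnitude; concentrates strength in the top
                     connections with the ordering intact (entropy-type).

Effects marked ``trait`` apply to both smoker sessions, ``abstinent_only``
effects to the abstinent session alone.  Motion is emulated with smooth
parameter drift plus Poisson-like spikes: spike frames exceed the 0.5 mm
framewise-displacement threshold and carry large global artifacts (so
censoring has a real job), and a subthreshold motion-coupled leak ties
connectivity mildly to subject motion level (so the group-level FD
adjustment has a real job).  Optional high-motion subjects exceed the 25%
censoring-exclusion rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import io as cio
from .io import ConfoundTable, SubjectRecord, VoxelGrid

EFFECT_TYPES = ("gain", "rank_permutation", "concentration")
EFFECT_LABELS = {"gain": 1, "rank_permutation": 2, "concentration": 3}


@dataclass
class PlantedRegion:
    """Spherical region of planted misconfiguration (centre/radius in voxel
    units)."""

    center: tuple[float, float, float]
    radius: float
    effect: str
    size: float
    state: str = "trait"     # trait | abstinent_only

    def __post_init__(self):
        if self.effect not in EFFECT_TYPES:
            raise ValueError(f"unknown effect type {self.effect!r}")
        if self.size < 0:
            raise ValueError("effect size must be >= 0")
        if self.state not in ("trait", "abstinent_only"):
            raise ValueError(f"unknown effect state {self.state!r}")


def _default_regions() -> list[PlantedRegion]:
    return [
        PlantedRegion((3.4, 4.4, 5.5), 1.8, "gain", 4.0, "abstinent_only"),
        PlantedRegion((7.6, 4.4, 5.5), 1.8, "rank_permutation", 16,
                      "trait"),
        PlantedRegion((5.5, 7.4, 5.5), 1.8, "concentration", 0.7,
                      "abstinent_only"),
    ]


@dataclass
class ScenarioConfig:
    """Defaults define the desk-scale study conditions.

    Group sizes scale the empirical design down (20 two-session smokers vs
    15 nonsmokers, 35-subject matched normative pool); sessions are 8-min
    TR-2 scans (240 frames).  The fingerprint ladder, signal fraction,
    gain jitter and planted effect sizes together define a regime in which
    each planted effect type is recoverable predominantly by its matching
    metric.
    """

    n_smokers: int = 20
    n_nonsmokers: int = 15
    n_normative: int = 35
    n_high_motion_smokers: int = 1
    n_high_motion_nonsmokers: int = 1
    shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size: tuple[float, float, float] = (3.4, 3.4, 4.0)
    mask_center: tuple[float, float, float] = (5.5, 5.5, 5.5)
    mask_radius: float = 3.9
    n_targets: int = 30
    n_frames: int = 240
    tr: float = 2.0
    #: structural fingerprint ladder in Fisher-Z units: z_t = z0 + step * t
    ladder_z0: float = 0.15
    ladder_step: float = 0.014
    #: fraction of voxel variance carried by the structured signal
    signal_fraction: float = 0.55
    #: sd of the per-(session, voxel) multiplicative gain jitter
    gain_jitter_sd: float = 0.30
    #: sd (Fisher-Z units) of per-cell weight jitter
    weight_jitter_sd: float = 0.03
    #: sd (Fisher-Z units) of the fixed per-voxel fingerprint-template
    #: jitter, shared by every subject (fingerprints genuinely vary over
    #: the striatum; this also smooths the pooled rank-metric null)
    template_jitter_sd: float = 0.01
    #: latent band limits (Hz)
    band: tuple[float, float] = (0.01, 0.1)
    planted: list[PlantedRegion] = field(default_factory=_default_regions)
    #: per-frame motion spike probability range across ordinary subjects
    spike_rate_range: tuple[float, float] = (0.01, 0.05)
    high_motion_spike_rate: float = 0.25
    #: amplitude of the global artifact added at spike frames (signal units)
    spike_artifact_amp: float = 3.0
    #: amplitude of the subthreshold motion-coupled leak
    fd_leak: float = 0.15
    #: loading of WM/CSF nuisance signals on voxel series
    nuisance_amp: float = 0.10
    #: planted effect sizes are scaled per smoker by
    #: lo + (hi - lo) * severity, tying effect magnitude to the severity
    #: scores in the manifest
    severity_modulation: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    @property
    def noise_sd(self) -> float:
        """Private broadband noise sd relative to unit signal variance."""
        return float(np.sqrt(1.0 - self.signal_fraction))

    def ladder(self) -> np.ndarray:
        return self.ladder_z0 + self.ladder_step * np.arange(self.n_targets)

    def validate(self) -> None:
        if self.n_targets < 2 or self.n_frames < 30:
            raise ValueError("invalid scenario: too few targets or frames")
        if not 0 < self.signal_fraction < 1:
            raise ValueError("signal_fraction must be in (0, 1)")
        for r in self.planted:
            pass  # PlantedRegion validates itself


@dataclass
class GroundTruth:
    """Per-voxel planted-effect labels and per-subject generative truth."""

    labels: np.ndarray                 # (n_mask,) 0=none, else EFFECT_LABELS
    region_voxels: dict[str, np.ndarray]
    region_states: dict[str, str]
    severities: dict[str, float]       # smoker effect-magnitude modulators
    grid: VoxelGrid

    def to_json(self) -> str:
        return json.dumps({
            "labels": self.labels.tolist(),
            "region_voxels": {k: v.tolist()
                              for k, v in self.region_voxels.items()},
            "region_states": self.region_states,
            "severities": self.severities,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str, grid: VoxelGrid) -> "GroundTruth":
        d = json.loads(text)
        return cls(labels=np.asarray(d["labels"], dtype=int),
                   region_voxels={k: np.asarray(v, dtype=int)
                                  for k, v in d["region_voxels"].items()},
                   region_states=d["region_states"],
                   severities=d["severities"], grid=grid)


# ---------------------------------------------------------------------------
# geometry and latent machinery
# ---------------------------------------------------------------------------

def _ball_indices(shape, center, radius) -> np.ndarray:
    grid = np.indices(shape).reshape(3, -1).T
    d = np.linalg.norm(grid - np.asarray(center), axis=1)
    return grid[d <= radius]


def _band_limited(rng: np.random.Generator, n_series: int, n_frames: int,
                  tr: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance series with (approximately) band-limited spectra."""
    x = rng.standard_normal((n_series, n_frames))
    nyq = 0.5 / tr
    lo = max(band[0] / nyq, 1e-4)
    hi = min(band[1] / nyq, 0.99)
    b, a = sp_signal.butter(3, [lo, hi], btype="band")
    y = sp_signal.filtfilt(b, a, x, axis=-1)
    y = y - y.mean(axis=-1, keepdims=True)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _ladder_decomposition(ladder_z: np.ndarray) -> tuple[float, float, float]:
    """Latent-space decomposition reproducing a structural correlation
    ladder R_t = tanh(z_t).

    Targets are s_t = sqrt(rho) c + sqrt(1-rho) u_t.  The voxel signal is
    a*c + sum_t b_t u_t + d*private with unit variance, where
    b_t = (R_t - x) / sqrt(1 - rho) and x = a sqrt(rho).  The shared
    loading x is set at the value minimising the variance the structured
    part consumes, x = mean(R) - sqrt(var(R) / (T - 1)); the weakest
    targets then carry slightly negative unique-part weights, i.e. their
    positive overall correlation with the voxel rides on the shared
    frontal component — the usual situation for weak connections in real
    resting-state data.  rho follows as x / (x + ||R - x||).
    Returns (rho, a, d).
    """
    R = np.tanh(np.asarray(ladder_z, dtype=float))
    n = R.size
    v = float(R.var())
    x = float(R.mean() - np.sqrt(v / max(n - 1, 1))) if v > 0 else float(R[0])
    if x <= 0:
        raise ValueError("fingerprint ladder infeasible: shared loading "
                         "would be non-positive")
    s_norm = float(np.linalg.norm(R - x))
    rho = x / (x + s_norm) if s_norm else 0.5
    a = x / np.sqrt(rho)
    used = (x + s_norm) ** 2
    if used > 1.0:
        raise ValueError(
            f"fingerprint ladder infeasible: structured variance {used:.3f} "
            "> 1; reduce ladder spread or length")
    d = float(np.sqrt(1.0 - used))
    return float(rho), float(a), d, x


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

def _simulate_motion(rng: np.random.Generator, n_frames: int,
                     spike_rate: float, drift_scale: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Motion parameters, their derivatives and the FD series.

    Translations in mm, rotations in radians; FD is the usual sum of
    absolute parameter differences with rotations scaled by a 50 mm
    sphere radius.  Spikes are abrupt translation jumps large enough to
    push FD above 0.5 mm.
    """
    steps = rng.standard_normal((n_frames, 6)) * drift_scale
    steps[:, 3:] /= 50.0
    spikes = rng.random(n_frames) < spike_rate
    spikes[0] = False
    jump = rng.uniform(0.7, 1.6, size=(n_frames, 3)) * np.where(
        rng.random((n_frames, 3)) < 0.5, -1.0, 1.0)
    steps[:, :3] += np.where(spikes[:, None], jump / 3.0, 0.0) * 3.0
    motion = np.cumsum(steps, axis=0)
    derivs = np.vstack([np.zeros(6), np.diff(motion, axis=0)])
    fd = np.abs(derivs[:, :3]).sum(axis=1) + 50.0 * np.abs(derivs[:, 3:]).sum(axis=1)
    fd[0] = 0.0
    return motion, derivs, fd


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _target_blocks(shape: tuple[int, int, int], T: int) -> list[np.ndarray]:
    """T disjoint 2x2x1 target blocks rastered over the top and bottom
    z-slices (well outside the central striatal ball)."""
    sites = []
    for z in (0, shape[2] - 1):
        for y0 in range(0, shape[1] - 1, 3):
            for x0 in range(0, shape[0] - 1, 3):
                sites.append((x0, y0, z))
    if T > len(sites):
        raise ValueError(f"grid too small for {T} target blocks")
    # interleave the two planes so target order alternates hemispheres-like
    half = len(sites) // 2
    order = [sites[i // 2 + (i % 2) * half] for i in range(T)]
    return [np.array([[x0 + dx, y0 + dy, z]
                      for dx in (0, 1) for dy in (0, 1)])
            for x0, y0, z in order]


def _apply_effect_rows(z: np.ndarray, effect: str, size: float) -> np.ndarray:
    """Apply a rank-permutation or concentration effect to per-voxel
    ladder rows (V, T)."""
    T = z.shape[1]
    if effect == "rank_permutation":
        m = max(0, min(int(round(size)), T))
        start = (T - m) // 2
        perm = np.arange(T)
        perm[start:start + m] = perm[start:start + m][::-1]
        return z[:, perm]
    if effect == "concentration":
        # temperature sharpening of the weight ladder, preserving total
        # magnitude (sum of weights) so aggregate strength changes little
        # while strength concentrates in the top connections
        out = z ** (1.0 + size)
        out *= z.sum(1, keepdims=True) / out.sum(1, keepdims=True)
        return out
    return z


def _session_weights(rng, cfg: ScenarioConfig, template_z: np.ndarray,
                     planted: list[PlantedRegion],
                     region_voxels: dict[str, np.ndarray],
                     apply_abstinent: bool, is_smoker: bool,
                     severity: float) -> tuple[np.ndarray, np.ndarray, float,
                                               np.ndarray]:
    """Per-voxel latent weights for one session.

    Returns (a per voxel, B (V, T) weights on unique parts, d private
    loading, gain multiplier per voxel).
    """
    ladder = cfg.ladder()
    rho, a0, d, x = _ladder_decomposition(ladder)
    n_vox, T = template_z.shape

    z = template_z.copy()
    gain_mult = np.ones(n_vox)
    if is_smoker:
        lo, hi = cfg.severity_modulation
        mod = lo + (hi - lo) * severity
        for reg in planted:
            if reg.state == "abstinent_only" and not apply_abstinent:
                continue
            vox = region_voxels[reg.effect]
            if reg.effect == "gain":
                gain_mult[vox] = 1.0 + reg.size * mod
            else:
                size = (reg.size * mod if reg.effect == "concentration"
                        else reg.size)
                z[vox] = _apply_effect_rows(z[vox], reg.effect, size)

    z = z + cfg.weight_jitter_sd * rng.standard_normal((n_vox, T))
    R = np.tanh(z)
    B = (R - x) / np.sqrt(1.0 - rho)
    a = np.full(n_vox, a0)
    return a, B, d, gain_mult


def _write_session(rng, cfg: ScenarioConfig, grid: VoxelGrid,
                   target_blocks: list[np.ndarray], truth: GroundTruth,
                   template_z: np.ndarray, rec: SubjectRecord,
                   spike_rate: float, out_dir: Path,
                   is_smoker: bool, severity: float) -> None:
    F, T = cfg.n_frames, cfg.n_targets
    n_vox = grid.n_voxels
    rho, _, _, _ = _ladder_decomposition(cfg.ladder())

    # latent series
    c = _band_limited(rng, 1, F, cfg.tr, cfg.band)[0]
    U = _band_limited(rng, T, F, cfg.tr, cfg.band)
    wmcsf = _band_limited(rng, 2, F, cfg.tr, cfg.band)
    S_lat = np.sqrt(rho) * c + np.sqrt(1.0 - rho) * U    # (T, F)

    # motion + artifacts
    motion, derivs, fd = _simulate_motion(rng, F, spike_rate,
                                          drift_scale=0.02)
    spike_frames = fd > 0.55
    artifact = rng.standard_normal(F) * cfg.spike_artifact_amp * spike_frames
    leak = cfg.fd_leak * np.clip(fd / 0.5, 0, 1.0) * rng.standard_normal(F)

    a, B, d_load, gain_mult = _session_weights(
        rng, cfg, template_z, cfg.planted, truth.region_voxels,
        apply_abstinent=(rec.state == "abstinent"), is_smoker=is_smoker,
        severity=severity)

    priv = rng.standard_normal((n_vox, F))
    v_sig = a[:, None] * c[None, :] + B @ U + d_load * priv
    norm = np.sqrt(a ** 2 + (B ** 2).sum(1) + d_load ** 2)
    v_sig /= norm[:, None]

    gain = np.clip(1.0 + cfg.gain_jitter_sd * rng.standard_normal(n_vox),
                   0.2, None) * gain_mult
    noise = rng.standard_normal((n_vox, F))
    voxel_ts = (np.sqrt(cfg.signal_fraction) * gain[:, None] * v_sig
                + cfg.noise_sd * noise
                + cfg.nuisance_amp * (wmcsf[0] + wmcsf[1])[None, :]
                + (artifact + leak)[None, :])

    # assemble full 4D volume: background noise, target blocks, mask voxels
    vol = rng.standard_normal(cfg.shape + (F,)).astype(np.float32) * 0.5
    for t, blk in enumerate(target_blocks):
        series = (S_lat[t] + artifact + leak
                  + 0.05 * rng.standard_normal((len(blk), F)))
        vol[blk[:, 0], blk[:, 1], blk[:, 2], :] = series.astype(np.float32)
    vol[tuple(grid.mask_indices.T)] = voxel_ts.astype(np.float32)

    sid = rec.subject_id
    cio.write_volume(out_dir / "bold" / f"{sid}_{rec.state}_bold.nii",
                     vol, grid)
    conf = ConfoundTable(fd=fd, motion=motion, motion_derivs=derivs,
                         wm=wmcsf[0] + 0.02 * rng.standard_normal(F),
                         csf=wmcsf[1] + 0.02 * rng.standard_normal(F))
    cio.write_confounds(
        out_dir / "confounds" / f"{sid}_{rec.state}_confounds.tsv", conf)


def generate_dataset(cfg: ScenarioConfig, out_dir: str | Path
                     ) -> tuple[list[SubjectRecord], list[SubjectRecord],
                                GroundTruth]:
    """Write a complete synthetic dataset and return
    (empirical manifest records, normative records, ground truth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    (out_dir / "bold").mkdir(parents=True, exist_ok=True)
    (out_dir / "confounds").mkdir(parents=True, exist_ok=True)

    affine = np.diag(list(cfg.voxel_size) + [1.0])
    # centre the world origin on the mask centre
    affine[:3, 3] = -np.asarray(cfg.mask_center) * np.asarray(cfg.voxel_size)
    mask_idx = _ball_indices(cfg.shape, cfg.mask_center, cfg.mask_radius)
    grid = VoxelGrid(shape=cfg.shape, affine=affine, mask_indices=mask_idx)

    # planted regions -> in-mask voxel indices, checked disjoint and in-mask
    flat_mask = {tuple(v): i for i, v in enumerate(grid.mask_indices)}
    labels = np.zeros(grid.n_voxels, dtype=int)
    region_voxels: dict[str, np.ndarray] = {}
    region_states: dict[str, str] = {}
    for reg in cfg.planted:
        ball = _ball_indices(cfg.shape, reg.center, reg.radius)
        idx = []
        for v in ball:
            key = tuple(v)
            if key not in flat_mask:
                raise ValueError(f"planted region {reg.effect} extends "
                                 "outside the striatal mask")
            idx.append(flat_mask[key])
        idx = np.array(sorted(idx), dtype=int)
        if np.any(labels[idx] != 0):
            raise ValueError("planted regions overlap")
        labels[idx] = EFFECT_LABELS[reg.effect]
        region_voxels[reg.effect] = idx
        region_states[reg.effect] = reg.state

    target_blocks = _target_blocks(cfg.shape, cfg.n_targets)

    # masks / target label volume
    cio.write_map(out_dir / "striatal_mask.nii",
                  np.ones(grid.n_voxels), grid)
    tvol = np.zeros(cfg.shape)
    for t, blk in enumerate(target_blocks):
        tvol[blk[:, 0], blk[:, 1], blk[:, 2]] = t + 1
    cio.write_volume(out_dir / "targets.nii", tvol, grid)

    # subjects
    def demo(gid: str, group: str, state: str, ftnd=None, withdrawal=None):
        return SubjectRecord(
            subject_id=gid, group=group, state=state,
            age=float(np.round(np.clip(rng.normal(38, 11), 18, 55), 1)),
            sex="male" if rng.random() < 0.55 else "female",
            education=float(np.round(np.clip(rng.normal(13, 2), 8, 20), 1)),
            ftnd=ftnd, withdrawal=withdrawal)

    severities: dict[str, float] = {}
    records: list[SubjectRecord] = []
    n_smk = cfg.n_smokers + cfg.n_high_motion_smokers
    n_ctl = cfg.n_nonsmokers + cfg.n_high_motion_nonsmokers
    for i in range(n_smk):
        sid = f"smk{i + 1:02d}"
        sev = float(rng.uniform(0, 1))
        severities[sid] = sev
        ftnd = float(np.clip(np.round(2 + 6 * sev + rng.normal(0, 1)), 0, 10))
        wd = float(np.round(6 + 6 * sev + rng.normal(0, 1.2), 2))
        base = demo(sid, "smoker", "sated", ftnd=ftnd)
        records.append(base)
        records.append(SubjectRecord(
            subject_id=sid, group="smoker", state="abstinent", age=base.age,
            sex=base.sex, education=base.education, ftnd=ftnd, withdrawal=wd))
    for i in range(n_ctl):
        records.append(demo(f"ctl{i + 1:02d}", "nonsmoker", "single"))
    normative = [demo(f"nrm{i + 1:02d}", "nonsmoker", "single")
                 for i in range(cfg.n_normative)]

    truth = GroundTruth(labels=labels, region_voxels=region_voxels,
                        region_states=region_states, severities=severities,
                        grid=grid)

    # fixed per-voxel fingerprint templates, shared by all subjects and by
    # the normative pool (a matched cohort shares the anatomy)
    template_z = (cfg.ladder()[None, :] + cfg.template_jitter_sd
                  * rng.standard_normal((grid.n_voxels, cfg.n_targets)))

    lo, hi = cfg.spike_rate_range
    for rec in records + normative:
        i_high_smk = int(rec.subject_id[3:]) > cfg.n_smokers \
            if rec.subject_id.startswith("smk") else False
        i_high_ctl = int(rec.subject_id[3:]) > cfg.n_nonsmokers \
            if rec.subject_id.startswith("ctl") else False
        if i_high_smk or i_high_ctl:
            rate = cfg.high_motion_spike_rate
        else:
            rate = float(rng.uniform(lo, hi))
        _write_session(rng, cfg, grid, target_blocks, truth, template_z, rec,
                       spike_rate=rate, out_dir=out_dir,
                       is_smoker=rec.group == "smoker",
                       severity=severities.get(rec.subject_id, 0.0))

    cio.write_manifest(out_dir / "manifest.csv", records)
    cio.write_manifest(out_dir / "normative_manifest.csv", normative)
    (out_dir / "ground_truth.json").write_text(truth.to_json())
    cio.write_map(out_dir / "ground_truth_labels.nii",
                  labels.astype(float), grid)
    return records, normative, truth


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(significance_masks: dict[tuple[str, str], np.ndarray],
                      truth: GroundTruth) -> pd.DataFrame:
    """Sensitivity/specificity of significance masks vs the planted truth.

    ``significance_masks`` maps (metric, comparison) to a boolean per-voxel
    mask.  For every mask and every planted effect type the fraction of
    region voxels detected is reported (sensitivity for the matching
    metric, cross-detection otherwise), along with specificity over
    unplanted voxels.
    """
    rows = []
    clean = truth.labels == 0
    for (metric, comparison), mask in significance_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != truth.labels.shape:
            raise ValueError("mask not aligned to ground-truth grid")
        spec = 100.0 * (1.0 - mask[clean].mean()) if clean.any() else np.nan
        for effect, vox in truth.region_voxels.items():
            rows.append({
                "metric": metric, "comparison": comparison,
                "effect": effect, "effect_state": truth.region_states[effect],
                "sensitivity_pct": 100.0 * mask[vox].mean(),
                "specificity_pct": spec,
            })
    return pd.DataFrame(rows)
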