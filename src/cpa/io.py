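"""Reading, writing and validation of the standard on-disk formats.

Volumes are NIfTI-1 (read through nibabel and reoriented to RAS+ on load),
confound tables are TSV with one row per frame, and the subject manifest is a
CSV with a fixed schema.  All voxel-wise matrices downstream of this module
are aligned to a :class:`VoxelGrid`, whose in-mask voxel ordering is fixed
(lexicographic by x, y, z) and therefore reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("cpa")

GROUPS = ("smoker", "nonsmoker")
STATES = ("sated", "abstinent", "single")
SEXES = ("male", "female")

#: required manifest columns; extra columns are ignored
MANIFEST_COLUMNS = ("subject_id", "group", "state", "age", "sex", "education")

#: confound TSV column names (fmriprep-style naming)
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
MOTION_DERIV_COLUMNS = tuple(c + "_derivative1" for c in MOTION_COLUMNS)
CONFOUND_COLUMNS = (
    ("framewise_displacement",) + MOTION_COLUMNS + MOTION_DERIV_COLUMNS
    + ("white_matter", "csf")
)


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """A voxel grid with an optional ordered in-mask voxel set.

    ``mask_indices`` is an (n, 3) integer array of voxel coordinates sorted
    lexicographically by (x, y, z); every voxel-wise vector or matrix in the
    package is ordered identically.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    mask_indices: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be a 4x4 matrix")
        if self.mask_indices is not None:
            idx = np.asarray(self.mask_indices, dtype=np.intp)
            if idx.ndim != 2 or idx.shape[1] != 3:
                raise FormatError("mask_indices must be an (n, 3) array")
            if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
                raise FormatError("mask_indices out of grid bounds")
            order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
            idx = idx[order]
            if len(np.unique(idx, axis=0)) != len(idx):
                raise FormatError("mask_indices contains duplicates")
            object.__setattr__(self, "mask_indices", idx)

    @property
    def n_voxels(self) -> int:
        if self.mask_indices is None:
            return int(np.prod(self.shape))
        return len(self.mask_indices)

    def index_checksum(self) -> int:
        """Checksum of the in-mask voxel ordering, used to assert alignment."""
        if self.mask_indices is None:
            raise ValueError("grid has no mask")
        return int(np.ravel_multi_index(self.mask_indices.T, self.shape).sum())

    def world_coords(self, voxel_indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world (mm) coordinates via the affine."""
        ijk = np.atleast_2d(np.asarray(voxel_indices, dtype=float))
        hom = np.column_stack([ijk, np.ones(len(ijk))])
        return (self.affine @ hom.T).T[:, :3]

    def compatible_with(self, other: "VoxelGrid") -> bool:
        ok = self.shape == other.shape and np.allclose(self.affine, other.affine)
        if ok and self.mask_indices is not None and other.mask_indices is not None:
            ok = (self.mask_indices.shape == other.mask_indices.shape
                  and bool(np.all(self.mask_indices == other.mask_indices)))
        return ok

    def embed(self, values: np.ndarray, background: float = 0.0) -> np.ndarray:
        """Place a per-in-mask-voxel vector into a full 3D volume."""
        if self.mask_indices is None:
            raise ValueError("grid has no mask")
        vol = np.full(self.shape, background, dtype=float)
        vol[tuple(self.mask_indices.T)] = values
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Read the in-mask voxels of a 3D (or 4D) volume in grid order."""
        if self.mask_indices is None:
            raise ValueError("grid has no mask")
        return volume[tuple(self.mask_indices.T)]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    state: str
    age: float
    sex: str
    education: float
    ftnd: float | None = None
    withdrawal: float | None = None
    mean_fd: float | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise FormatError(f"unknown group label {self.group!r}")
        if self.state not in STATES:
            raise FormatError(f"unknown state label {self.state!r}")
        if self.sex not in SEXES:
            raise FormatError(f"unknown sex label {self.sex!r}")
        if self.group == "nonsmoker" and self.state != "single":
            raise FormatError(
                f"nonsmoker {self.subject_id} must have state='single', "
                f"got {self.state!r}")
        if self.group == "smoker" and self.state == "single":
            raise FormatError(
                f"smoker {self.subject_id} sessions must be sated/abstinent")
        if self.ftnd is not None and not (0 <= self.ftnd <= 10):
            raise FormatError(f"ftnd {self.ftnd} outside 0-10")


@dataclass
class ConfoundTable:
    """Per-frame nuisance measurements for one session."""

    fd: np.ndarray
    motion: np.ndarray
    motion_derivs: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self):
        self.fd = np.asarray(self.fd, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.motion_derivs = np.asarray(self.motion_derivs, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        n = self.n_frames
        for name in ("motion", "motion_derivs"):
            arr = getattr(self, name)
            if arr.shape != (n, 6):
                raise FormatError(f"{name} must be (n_frames, 6)")
        for name in ("wm", "csf"):
            if getattr(self, name).shape != (n,):
                raise FormatError(f"{name} length != n_frames")
        if np.any(self.fd < 0):
            raise FormatError("framewise displacement must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.fd)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_bold(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a 4D BOLD NIfTI, reorienting to RAS+.

    Returns the (x, y, z, t) data array (float64) and a maskless
    :class:`VoxelGrid` carrying the volume's shape and affine.
    """
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4D volume, got {img.ndim} dims")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.shape[3] < 1:
        raise FormatError(f"{path}: no frames")
    grid = VoxelGrid(shape=data.shape[:3], affine=img.affine)
    return data, grid


def read_mask(path: str | Path, reference: VoxelGrid | None = None) -> VoxelGrid:
    """Read a binary mask NIfTI into a VoxelGrid with ordered mask_indices."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    if img.ndim != 3:
        raise FormatError(f"{path}: mask must be 3D")
    data = np.asarray(img.get_fdata())
    if reference is not None:
        ref = VoxelGrid(shape=data.shape, affine=img.affine)
        if not ref.compatible_with(VoxelGrid(reference.shape, reference.affine)):
            raise FormatError(f"{path}: mask grid does not match reference")
    idx = np.argwhere(data > 0)
    if len(idx) == 0:
        raise FormatError(f"{path}: empty mask")
    return VoxelGrid(shape=data.shape, affine=img.affine, mask_indices=idx)


def read_targets(
    path: str | Path | Sequence[str | Path],
    expected_t: int,
) -> list[np.ndarray]:
    """Read the ordered frontal target set.

    ``path`` is either one labelled NIfTI volume (labels 1..T) or a sequence
    of T binary mask files.  Returns a list of T (n_i, 3) voxel-index arrays,
    ordered by label value / file order.  Overlapping targets are accepted
    with a logged warning.
    """
    if isinstance(path, (str, Path)):
        img = nib.as_closest_canonical(nib.load(str(path)))
        data = np.asarray(img.get_fdata()).round().astype(int)
        labels = sorted(int(v) for v in np.unique(data) if v > 0)
        if labels != list(range(1, expected_t + 1)):
            raise FormatError(
                f"expected labels 1..{expected_t}, found {labels}")
        return [np.argwhere(data == lab) for lab in labels]
    paths = list(path)
    if len(paths) != expected_t:
        raise FormatError(f"expected {expected_t} target masks, got {len(paths)}")
    targets, seen = [], None
    for p in paths:
        g = read_mask(p)
        targets.append(g.mask_indices)
        flat = set(np.ravel_multi_index(g.mask_indices.T, g.shape))
        if seen is not None and seen & flat:
            logger.warning("target masks overlap (%s); a voxel may serve two "
                           "targets", p)
        seen = (seen or set()) | flat
    return targets


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "n/a", "NA"):
        return None
    return float(value)


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read and validate the subject/session manifest CSV.

    One row per session.  Nonsmokers have exactly one ``single`` session;
    smokers have up to two sessions with distinct states.  A smoker with
    missing FTND is kept (the behaviour regression drops it later).
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            state=str(row["state"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            education=float(row["education"]),
            ftnd=_opt_float(row.get("ftnd")),
            withdrawal=_opt_float(row.get("withdrawal")),
            mean_fd=_opt_float(row.get("mean_fd")),
        ))
    by_subject: dict[str, list[SubjectRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    for sid, recs in by_subject.items():
        groups = {r.group for r in recs}
        if len(groups) > 1:
            raise FormatError(f"subject {sid} appears in multiple groups")
        states = [r.state for r in recs]
        if len(states) != len(set(states)):
            raise FormatError(f"subject {sid} has duplicate session states")
        if recs[0].group == "nonsmoker" and len(recs) > 1:
            raise FormatError(f"nonsmoker {sid} must have exactly one session")
        if len(recs) > 2:
            raise FormatError(f"subject {sid} has more than two sessions")
    return records


def read_confounds(path: str | Path) -> ConfoundTable:
    """Read a tab-separated confound table (one row per frame).

    A missing framewise displacement in frame 0 (fmriprep writes ``n/a``)
    is treated as 0.
    """
    df = pd.read_csv(path, sep="\t", na_values=["n/a", "NA"])
    missing = [c for c in CONFOUND_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"confound table missing columns {missing}")
    fd = df["framewise_displacement"].to_numpy(dtype=float)
    if len(fd) and np.isnan(fd[0]):
        fd[0] = 0.0
    if np.any(np.isnan(fd)):
        raise FormatError("framewise displacement contains missing values "
                          "beyond frame 0")
    return ConfoundTable(
        fd=fd,
        motion=df[list(MOTION_COLUMNS)].to_numpy(dtype=float),
        motion_derivs=df[list(MOTION_DERIV_COLUMNS)].to_numpy(dtype=float),
        wm=df["white_matter"].to_numpy(dtype=float),
        csf=df["csf"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_volume(path: str | Path, volume: np.ndarray, grid: VoxelGrid) -> None:
    """Write a 3D/4D array as NIfTI with the grid's affine (float64 data,
    so written maps round-trip bit-identically)."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), grid.affine)
    nib.save(img, str(path))


def write_map(path: str | Path, values: np.ndarray, grid: VoxelGrid,
              background: float = 0.0) -> None:
    """Write a per-in-mask-voxel vector as a full 3D NIfTI volume."""
    write_volume(path, grid.embed(values, background=background), grid)


def write_confounds(path: str | Path, conf: ConfoundTable) -> None:
    cols = {"framewise_displacement": conf.fd}
    for i, c in enumerate(MOTION_COLUMNS):
        cols[c] = conf.motion[:, i]
    for i, c in enumerate(MOTION_DERIV_COLUMNS):
        cols[c] = conf.motion_derivs[:, i]
    cols["white_matter"] = conf.wm
    cols["csf"] = conf.csf
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, records: Sequence[SubjectRecord]) -> None:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "group": r.group, "state": r.state,
            "age": r.age, "sex": r.sex, "education": r.education,
            "ftnd": r.ftnd, "withdrawal": r.withdrawal, "mean_fd": r.mean_fd,
        })
    columns = list(MANIFEST_COLUMNS) + ["ftnd", "withdrawal", "mean_fd"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
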