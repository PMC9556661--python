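"""From preprocessed BOLD + confounds to voxel-by-target Fisher-Z fingerprints.

The stages mirror standard seed-based resting-state practice: motion
censoring (framewise-displacement scrubbing), a nuisance GLM per seed
(6 motion parameters + 6 derivatives + white matter + CSF + polynomial
trend; 17 regressors with the defaults), Fisher r-to-Z transformation, and
a group-level adjustment for residual head-motion differences (regressing
each voxel-by-target Z cell on subject mean FD across subjects).

The per-seed GLM is computed as a partial correlation: both the voxel and
the seed series are residualised on the nuisance matrix over the retained
frames, and the Pearson correlation of the residuals is taken.  This is
algebraically the standardised GLM output and stays in [-1, 1], so the
Fisher transform is always defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ConfoundTable, VoxelGrid

logger = logging.getLogger("cpa")

#: clipping bound for |r| before the Fisher transform
FISHER_EPS = 1e-7

DEFAULT_FD_THRESHOLD = 0.5   # mm
DEFAULT_N_LEADING = 3        # frames
DEFAULT_MAX_CENSORED = 0.25  # proportion
DEFAULT_POLY_ORDER = 2


@dataclass
class FrameMask:
    """Boolean per-frame retention mask produced by censoring."""

    keep: np.ndarray

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 1 or self.keep.size == 0:
            raise ValueError("keep must be a non-empty 1D boolean array")

    @property
    def n_frames(self) -> int:
        return self.keep.size

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())

    @property
    def fraction_censored(self) -> float:
        return self.n_censored / self.n_frames


@dataclass
class ZScoreMap:
    """Per-session (n_voxels, T) matrix of Fisher-Z connectivity strengths."""

    subject_id: str
    state: str
    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_voxels, T)")
        if self.values.shape[0] != self.grid.n_voxels:
            raise ValueError("row count does not match grid mask")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Z scores must be finite")

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# censoring
# ---------------------------------------------------------------------------

def censor_frames(fd: np.ndarray,
                  fd_threshold: float = DEFAULT_FD_THRESHOLD,
                  n_leading: int = DEFAULT_N_LEADING) -> FrameMask:
    """Censor high-motion frames.

    Censored frames are the union of: frames with FD > ``fd_threshold``,
    frames immediately preceding those, and the first ``n_leading`` frames.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty framewise-displacement series")
    if fd.size < n_leading:
        raise ValueError("fewer frames than n_leading")
    supra = fd > fd_threshold
    censored = supra.copy()
    censored[:-1] |= supra[1:]        # frame preceding a supra-threshold frame
    censored[:n_leading] = True
    return FrameMask(keep=~censored)


def check_exclusion(mask: FrameMask,
                    max_fraction: float = DEFAULT_MAX_CENSORED) -> bool:
    """True if the session is retained: fails only when *more than*
    ``max_fraction`` of frames were censored (strict inequality)."""
    return not (mask.fraction_censored > max_fraction)


# ---------------------------------------------------------------------------
# nuisance model
# ---------------------------------------------------------------------------

def _poly_basis(n: int, order: int) -> np.ndarray:
    """Discrete orthonormal polynomial columns (degree 0..order) over n
    points — a Legendre-style trend basis, exactly orthogonal over the
    frames it is built on."""
    x = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    V = np.vander(x, order + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    # fix signs so the basis is reproducible (leading coefficient positive)
    return Q * np.sign(np.diag(R))


def build_nuisance(conf: ConfoundTable,
                   keep: FrameMask | None = None,
                   poly_order: int = DEFAULT_POLY_ORDER) -> np.ndarray:
    """Assemble the nuisance regressor matrix over the retained frames.

    Columns: 6 motion + 6 motion derivatives + white matter + CSF +
    (poly_order + 1) polynomial trend columns — 17 with the defaults.  The
    polynomial basis is constructed on the retained frames only, so its
    columns are mutually orthogonal after censoring.  Constant-zero
    regressor columns are dropped with a warning.
    """
    keep_idx = (np.arange(conf.n_frames) if keep is None
                else np.flatnonzero(keep.keep))
    cols = [conf.motion[keep_idx], conf.motion_derivs[keep_idx],
            conf.wm[keep_idx, None], conf.csf[keep_idx, None]]
    X = np.column_stack([np.column_stack(cols),
                         _poly_basis(len(keep_idx), poly_order)])
    zero = np.all(X == 0, axis=0)
    if np.any(zero):
        logger.warning("dropping %d constant-zero nuisance column(s)",
                       int(zero.sum()))
        X = X[:, ~zero]
    return X


# ---------------------------------------------------------------------------
# seed connectivity
# ---------------------------------------------------------------------------

def _residualise(Y: np.ndarray, X: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of Y on the design X (demeaning when X is
    empty or absent)."""
    if X is None or X.size == 0:
        return Y - Y.mean(axis=0, keepdims=True)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    # keep residuals mean-free even when X lacks an explicit intercept
    return R - R.mean(axis=0, keepdims=True)


def seed_connectivity(voxel_ts: np.ndarray, seed_ts: np.ndarray,
                      nuisance: np.ndarray | None = None,
                      keep: FrameMask | None = None) -> float:
    """Partial Pearson correlation of one voxel and one seed series.

    Censored frames are dropped; both series are residualised on the
    nuisance matrix (which must already be restricted to retained frames
    when ``keep`` is given); r is the Pearson correlation of the residuals.
    """
    r = fingerprint_matrix(np.atleast_2d(voxel_ts), np.atleast_2d(seed_ts),
                           nuisance=nuisance, keep=keep)
    return float(r[0, 0])


def fingerprint_matrix(voxel_ts: np.ndarray, target_ts: np.ndarray,
                       nuisance: np.ndarray | None = None,
                       keep: FrameMask | None = None) -> np.ndarray:
    """Partial correlations of every voxel series with every target series.

    ``voxel_ts`` is (n_voxels, n_frames), ``target_ts`` is (T, n_frames);
    returns an (n_voxels, T) matrix of r values.  One model per seed: the
    nuisance design is shared, so residualising all series once is
    equivalent to the per-seed GLM.
    """
    V = np.asarray(voxel_ts, dtype=float)
    S = np.asarray(target_ts, dtype=float)
    if V.shape[1] != S.shape[1]:
        raise ValueError("voxel and seed series lengths differ")
    if keep is not None:
        V = V[:, keep.keep]
        S = S[:, keep.keep]
    n = V.shape[1]
    rank = 0
    if nuisance is not None and nuisance.size:
        X = np.asarray(nuisance, dtype=float)
        if X.shape[0] != n:
            raise ValueError("nuisance rows must match retained frames")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError("degenerate design: nuisance matrix is "
                             "rank-deficient after censoring")
    else:
        X = None
    if n < rank + 2:
        raise ValueError("degenerate design: need at least 2 retained frames "
                         "more than the nuisance rank")
    Rv = _residualise(V.T, X)   # (frames, voxels)
    Rs = _residualise(S.T, X)   # (frames, targets)
    sv = np.linalg.norm(Rv, axis=0)
    ss = np.linalg.norm(Rs, axis=0)
    sv[sv == 0] = np.nan
    ss[ss == 0] = np.nan
    r = (Rv / sv).T @ (Rs / ss)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-Z transform, Z = atanh(r).

    |r| >= 1 is clipped to 1 - 1e-7 in magnitude with a warning (a pinned
    correlation carries no finite-variance information anyway).
    """
    arr = np.asarray(r, dtype=float)
    clip = np.abs(arr) >= 1.0 - FISHER_EPS
    if np.any(clip):
        logger.warning("clipping %d correlation(s) with |r| >= 1-%g before "
                       "Fisher transform", int(clip.sum()), FISHER_EPS)
        arr = np.clip(arr, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


# ---------------------------------------------------------------------------
# group-level adjustment and averaging
# ---------------------------------------------------------------------------

def fd_adjust(zmaps: list[ZScoreMap], mean_fd: np.ndarray) -> list[ZScoreMap]:
    """Adjust Z maps for between-subject head-motion differences.

    For each voxel-by-target cell, Z values across sessions are replaced by
    the residual of a linear fit of Z on mean-centred mean FD plus the
    fitted intercept, i.e. the Z expected at the grand-mean FD.  The
    cross-session mean of every cell is preserved exactly.
    """
    if len(zmaps) < 3:
        raise ValueError("fd_adjust requires at least 3 sessions")
    fd = np.asarray(mean_fd, dtype=float)
    if fd.shape != (len(zmaps),) or np.any(np.isnan(fd)):
        raise ValueError("mean_fd must be known for every session")
    fdc = fd - fd.mean()
    denom = (fdc ** 2).sum()
    if denom == 0:
        logger.warning("fd_adjust: zero variance in mean FD; returning maps "
                       "unchanged")
        return [ZScoreMap(m.subject_id, m.state, m.values.copy(), m.grid)
                for m in zmaps]
    Z = np.stack([m.values for m in zmaps])          # (S, V, T)
    slope = np.tensordot(fdc, Z, axes=(0, 0)) / denom  # (V, T)
    adjusted = Z - fdc[:, None, None] * slope[None]
    return [ZScoreMap(m.subject_id, m.state, adjusted[i], m.grid)
            for i, m in enumerate(zmaps)]


def group_average_fingerprints(
    zmaps: list[ZScoreMap],
    group_assignments: list[str],
) -> dict[str, np.ndarray]:
    """Cell-wise mean fingerprint map per group/state stratum."""
    if len(zmaps) != len(group_assignments):
        raise ValueError("one group label per Z map required")
    out: dict[str, list[np.ndarray]] = {}
    for m, g in zip(zmaps, group_assignments):
        out.setdefault(g, []).append(m.values)
    if not out:
        raise ValueError("no maps to average")
    return {g: np.mean(v, axis=0) for g, v in out.items()}
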