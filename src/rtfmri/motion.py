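"""Rigid-body head-motion estimation from intensity histograms.

Each incoming volume is registered to (a) a fixed reference volume from the
start of the run and (b) the previous volume, yielding absolute and relative
motion. Registration maximizes mutual information of the joint intensity
histogram (32 bins over jointly min-max scaled intensities) over the six
rigid-body parameters (3 translations in mm, 3 rotations in radians about
the volume center), using coordinate descent with two resolution levels.

The scalar reported per registration is the mean Euclidean displacement in
mm of in-brain voxel coordinates under the estimated transform, where the
brain support is the set of reference voxels above 10% of the reference's
robust (98th percentile) maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import VolumeGeometry

log = logging.getLogger(__name__)

__all__ = ["MotionEstimate", "estimate_motion", "estimate_rigid", "mean_displacement_mm"]

N_BINS = 32
BRAIN_FRACTION = 0.10


@dataclass(frozen=True)
class MotionEstimate:
    """Absolute (vs. run reference) and relative (vs. previous volume)
    mean displacement in mm for one timepoint."""

    vol_idx: int
    abs_disp_mm: float
    rel_disp_mm: float


def _scale_to_bins(a: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.zeros(a.shape, dtype=np.intp)
    scaled = (a - lo) / (hi - lo) * (N_BINS - 1)
    return np.clip(scaled, 0, N_BINS - 1).astype(np.intp)


def _mutual_information(a_bins: np.ndarray, b_bins: np.ndarray) -> float:
    joint = np.bincount(
        a_bins.ravel() * N_BINS + b_bins.ravel(), minlength=N_BINS * N_BINS
    ).reshape(N_BINS, N_BINS).astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float(
        (joint[nz] * np.log(joint[nz] / (pa[:, None] * pb[None, :])[nz])).sum()
    )


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _resample(moving: np.ndarray, params: np.ndarray, voxel_size: np.ndarray) -> np.ndarray:
    """Apply the rigid transform (world mm, about the volume center) to
    ``moving`` and resample on the fixed grid (linear interpolation)."""
    t = params[:3]
    R = _rotation_matrix(*params[3:])
    S = np.diag(voxel_size)
    Sinv = np.diag(1.0 / voxel_size)
    center = (np.asarray(moving.shape, dtype=float) - 1) / 2.0
    # fixed voxel v -> world w = S(v - c); moving sample = S^-1 R^-1 (w - t) + c
    A = Sinv @ R.T @ S
    offset = center - A @ center - Sinv @ (R.T @ t)
    return ndimage.affine_transform(
        moving, A, offset=offset, order=1, mode="constant", cval=0.0, prefilter=False
    )


def _brain_mask(ref: np.ndarray) -> np.ndarray:
    robust_max = np.percentile(ref, 98)
    mask = ref > BRAIN_FRACTION * robust_max
    if not mask.any():
        mask = np.ones(ref.shape, dtype=bool)
    return mask


def mean_displacement_mm(
    params: np.ndarray, mask: np.ndarray, voxel_size: np.ndarray
) -> float:
    """Mean |T(x) - x| in mm over in-brain voxel coordinates."""
    coords = np.argwhere(mask).astype(float)
    center = (np.asarray(mask.shape, dtype=float) - 1) / 2.0
    world = (coords - center) * voxel_size
    R = _rotation_matrix(*params[3:])
    moved = world @ R.T + params[:3]
    return float(np.linalg.norm(moved - world, axis=1).mean())


def _optimize_level(
    fixed_bins: np.ndarray,
    moving: np.ndarray,
    mov_lo: float,
    mov_hi: float,
    voxel_size: np.ndarray,
    params: np.ndarray,
    trans_steps: tuple[float, float],
    rot_steps: tuple[float, float],
) -> np.ndarray:
    """Coordinate descent over the 6 rigid parameters at one resolution."""

    def score(p: np.ndarray) -> float:
        resampled = _resample(moving, p, voxel_size)
        return _mutual_information(fixed_bins, _scale_to_bins(resampled, mov_lo, mov_hi))

    best = score(params)
    steps = np.array([trans_steps[0]] * 3 + [rot_steps[0]] * 3)
    floor = np.array([trans_steps[1]] * 3 + [rot_steps[1]] * 3)
    while np.any(steps >= floor):
        improved = False
        for i in range(6):
            if steps[i] < floor[i]:
                continue
            for sign in (1.0, -1.0):
                while True:
                    cand = params.copy()
                    cand[i] += sign * steps[i]
                    s = score(cand)
                    if s > best + 1e-9:
                        params, best = cand, s
                        improved = True
                    else:
                        break
        if not improved:
            steps *= 0.5
    return params


def estimate_rigid(
    moving: np.ndarray, fixed: np.ndarray, voxel_size_mm
) -> np.ndarray:
    """Estimate the 6 rigid parameters aligning ``moving`` to ``fixed``.

    Returns ``[tx, ty, tz, rx, ry, rz]`` (mm / radians). Identical inputs
    short-circuit to zero.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    voxel_size = np.asarray(voxel_size_mm, dtype=float)
    if np.array_equal(moving, fixed):
        return np.zeros(6)
    if fixed.std() == 0 or moving.std() == 0:
        log.warning("flat volume in motion estimation; reporting zero motion")
        return np.zeros(6)
    params = np.zeros(6)
    lo = min(fixed.min(), moving.min())
    hi = max(fixed.max(), moving.max())
    min_vox = float(voxel_size.min())

    # level 1: in-plane downsample by 2 for a cheap global search
    if min(moving.shape[0], moving.shape[1]) >= 16:
        ds = (slice(None, None, 2), slice(None, None, 2), slice(None))
        f_ds, m_ds = fixed[ds], moving[ds]
        vox_ds = voxel_size * np.array([2.0, 2.0, 1.0])
        fixed_bins = _scale_to_bins(f_ds, lo, hi)
        params = _optimize_level(
            fixed_bins, m_ds, lo, hi, vox_ds, params,
            trans_steps=(2.0 * min_vox, 0.25 * min_vox),
            rot_steps=(0.05, 0.01),
        )

    # level 2: full resolution refinement
    fixed_bins = _scale_to_bins(fixed, lo, hi)
    params = _optimize_level(
        fixed_bins, moving, lo, hi, voxel_size, params,
        trans_steps=(0.5 * min_vox, 0.05 * min_vox),
        rot_steps=(0.02, 0.002),
    )
    return params


def estimate_motion(
    v: np.ndarray,
    ref: np.ndarray,
    prev: np.ndarray,
    geom: VolumeGeometry,
    vol_idx: int = 0,
) -> MotionEstimate:
    """Absolute and relative mean displacement (mm) for one volume."""
    voxel_size = np.asarray(geom.voxel_size_mm, dtype=float)
    mask = _brain_mask(np.asarray(ref, dtype=float))
    abs_params = estimate_rigid(v, ref, voxel_size)
    abs_disp = mean_displacement_mm(abs_params, mask, voxel_size)
    if prev is ref or np.array_equal(prev, ref):
        rel_of = abs_params
    else:
        rel_of = estimate_rigid(v, prev, voxel_size)
    rel_disp = mean_displacement_mm(rel_of, mask, voxel_size)
    return MotionEstimate(vol_idx=vol_idx, abs_disp_mm=abs_disp, rel_disp_mm=rel_disp)
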