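"""Volume geometry and RAS+ reorientation.

Every volume handed to the analysis side is expressed in RAS+ axis order:
voxel indices increase toward the subject's Right, Anterior, and Superior.
Scanner dialects deliver data in whatever native orientation the acquisition
used; :func:`compute_ras_affine` derives the axis permutation/flip that maps
native voxel axes onto RAS+ while preserving every voxel's world coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from nibabel import orientations as nbo

from .errors import FormatError

__all__ = ["VolumeGeometry", "Reorientation", "compute_ras_affine"]


@dataclass
class VolumeGeometry:
    """Spatial metadata for one functional series.

    Parameters
    ----------
    dims : tuple of int
        Voxels per axis (x, y, z), each >= 1.
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm, all > 0.
    affine_ras : (4, 4) ndarray
        Voxel-index -> RAS+ world (mm) transform.
    expected_timepts : int or None
        Total volumes the scan should produce, when the header announces it.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine_ras: np.ndarray = field(default=None)  # type: ignore[assignment]
    expected_timepts: int | None = None

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must all be >= 1, got {self.dims}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size_mm}")
        if self.affine_ras is None:
            self.affine_ras = np.diag(list(self.voxel_size_mm) + [1.0])
        self.affine_ras = np.asarray(self.affine_ras, dtype=float)
        if self.affine_ras.shape != (4, 4):
            raise ValueError("affine_ras must be 4x4")
        if abs(np.linalg.det(self.affine_ras[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")

    @property
    def n_slices(self) -> int:
        return self.dims[2]


@dataclass(frozen=True)
class Reorientation:
    """Axis permutation/flip taking native voxel axes to RAS+ order.

    ``ornt`` follows the nibabel orientation convention: row i names the
    RAS+ output axis that native axis i feeds, and its direction (+1/-1).
    """

    ornt: np.ndarray

    def apply(self, data: np.ndarray) -> np.ndarray:
        return nbo.apply_orientation(data, self.ornt)

    def apply_shape(self, shape: tuple[int, ...]) -> tuple[int, ...]:
        out = [0, 0, 0]
        for native_ax, (out_ax, _flip) in enumerate(self.ornt):
            out[int(out_ax)] = int(shape[native_ax])
        return tuple(out)

    @property
    def is_identity(self) -> bool:
        return bool(
            np.array_equal(self.ornt[:, 0], [0, 1, 2])
            and np.all(self.ornt[:, 1] == 1)
        )


def compute_ras_affine(
    native_affine: np.ndarray, shape: tuple[int, int, int]
) -> tuple[Reorientation, np.ndarray]:
    """Find the axis shuffle that brings a volume into RAS+ order.

    Returns the :class:`Reorientation` operator plus the affine that maps the
    *reoriented* voxel grid to world mm. Composing the two preserves every
    voxel's world coordinate; the returned affine's dominant axis directions
    are +R, +A, +S.
    """
    native_affine = np.asarray(native_affine, dtype=float)
    if native_affine.shape != (4, 4) or abs(np.linalg.det(native_affine[:3, :3])) < 1e-12:
        raise FormatError("native affine must be an invertible 4x4 matrix")
    ornt = nbo.io_orientation(native_affine)
    affine_ras = native_affine @ nbo.inv_ornt_aff(ornt, shape)
    return Reorientation(ornt=ornt), affine_ras
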