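"""Vendor file dialects: watching, reading, and volume assembly.

Three scanner-side file conventions are supported:

``slice2d``
    One 2D DICOM file per slice (GE-style). Slices are grouped into volumes
    in contiguous blocks of ``n_slices`` by instance number, and stacked in
    ascending order of their position along the slice normal.
``mosaic``
    One DICOM file per volume with all slices tiled in a row-major square
    grid on a single 2D image (Siemens-style).
``parrec``
    One PAR (text header) + REC (raw binary) pair per timepoint
    (Philips-style), read through nibabel.

Assembled volumes are reoriented to RAS+ axis order before they leave this
module, so everything downstream is orientation-agnostic.
"""

from __future__ import annotations

import logging
import math
import os
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pydicom
from nibabel import parrec as nib_parrec

from .errors import FormatError
from .geometry import Reorientation, VolumeGeometry, compute_ras_affine

log = logging.getLogger(__name__)

__all__ = [
    "RawImageFile",
    "AssembledVolume",
    "watch_directory",
    "demosaic",
    "mosaicify",
    "stack_slices",
    "read_parrec",
    "read_dicom_slice",
    "read_dicom_mosaic",
    "make_assembler",
    "SliceAssembler",
    "MosaicAssembler",
    "ParRecAssembler",
]

DIALECTS = ("slice2d", "mosaic", "parrec")

# Private Siemens-style tag carrying the number of slices tiled in a mosaic.
MOSAIC_NSLICES_TAG = (0x0019, 0x100A)


@dataclass(frozen=True)
class RawImageFile:
    """One file observed in the scanner's export directory."""

    path: Path
    series_id: str
    arrival_order: int
    dialect: str


@dataclass
class AssembledVolume:
    """A complete 3D volume for a single timepoint, in RAS+ axis order."""

    vol_idx: int
    data: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if tuple(self.data.shape) != tuple(self.geometry.dims):
            raise ValueError(
                f"data shape {self.data.shape} != geometry dims {self.geometry.dims}"
            )


# ---------------------------------------------------------------------------
# directory watching
# ---------------------------------------------------------------------------

def watch_directory(
    path: str | Path,
    poll_interval: float = 0.05,
    dialect: str = "mosaic",
    stop_event=None,
    timeout: float | None = None,
    expected_count: int | None = None,
    ready_event=None,
) -> Iterator[RawImageFile]:
    """Poll ``path`` and yield each newly created file exactly once.

    Files already present when watching begins are not emitted. Within one
    poll cycle new files are emitted in lexicographic name order, which makes
    the stream deterministic for vendor-style zero-padded numbering.

    The generator ends when ``stop_event`` is set, ``timeout`` seconds have
    elapsed, or ``expected_count`` files have been emitted. ``ready_event``,
    if given, is set once the pre-existing baseline has been snapshotted,
    i.e. once every later file creation is guaranteed to be observed.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"watch directory does not exist: {path}")
    seen = {e.name for e in os.scandir(path)}
    if ready_event is not None:
        ready_event.set()
    arrival = 0
    deadline = None if timeout is None else time.monotonic() + timeout
    while True:
        if stop_event is not None and stop_event.is_set():
            return
        if deadline is not None and time.monotonic() > deadline:
            return
        try:
            names = sorted(e.name for e in os.scandir(path) if e.is_file())
        except FileNotFoundError:
            return
        for name in names:
            if name in seen:
                continue
            seen.add(name)
            yield RawImageFile(
                path=path / name,
                series_id=_series_id_from_name(name),
                arrival_order=arrival,
                dialect=dialect,
            )
            arrival += 1
            if expected_count is not None and arrival >= expected_count:
                return
        time.sleep(poll_interval)


def _series_id_from_name(name: str) -> str:
    """First underscore-delimited numeric token, else the stem."""
    stem = Path(name).stem
    for tok in stem.split("_"):
        if tok.isdigit():
            return tok
    return stem


# ---------------------------------------------------------------------------
# mosaics
# ---------------------------------------------------------------------------

def demosaic(
    mosaic: np.ndarray, slice_rows: int, slice_cols: int, n_slices: int
) -> np.ndarray:
    """Split a row-major tiled 2D mosaic into a (rows, cols, n_slices) stack.

    Tile at grid position (r, c) becomes slice ``r * grid_cols + c``; trailing
    blank tiles beyond ``n_slices`` are discarded.
    """
    mosaic = np.asarray(mosaic)
    if mosaic.ndim != 2:
        raise FormatError("mosaic must be a 2D array")
    if mosaic.shape[0] % slice_rows or mosaic.shape[1] % slice_cols:
        raise FormatError(
            f"mosaic dims {mosaic.shape} not divisible by tile {slice_rows}x{slice_cols}"
        )
    grid_r = mosaic.shape[0] // slice_rows
    grid_c = mosaic.shape[1] // slice_cols
    if n_slices > grid_r * grid_c:
        raise FormatError(f"n_slices={n_slices} exceeds grid capacity {grid_r * grid_c}")
    out = np.empty((slice_rows, slice_cols, n_slices), dtype=mosaic.dtype)
    for s in range(n_slices):
        r, c = divmod(s, grid_c)
        out[:, :, s] = mosaic[
            r * slice_rows : (r + 1) * slice_rows, c * slice_cols : (c + 1) * slice_cols
        ]
    return out


def mosaicify(vol: np.ndarray) -> np.ndarray:
    """Tile a 3D (rows, cols, slices) volume into one square row-major mosaic.

    Inverse of :func:`demosaic` with grid = ceil(sqrt(n_slices)) squared,
    blank (zero) trailing tiles.
    """
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise FormatError("volume must be 3D")
    rows, cols, n = vol.shape
    g = math.ceil(math.sqrt(n))
    out = np.zeros((rows * g, cols * g), dtype=vol.dtype)
    for s in range(n):
        r, c = divmod(s, g)
        out[r * rows : (r + 1) * rows, c * cols : (c + 1) * cols] = vol[:, :, s]
    return out


def infer_mosaic_grid(n_slices: int) -> int:
    """Square mosaic grid edge for ``n_slices`` tiles (standard convention)."""
    return math.ceil(math.sqrt(n_slices))


# ---------------------------------------------------------------------------
# slice stacking
# ---------------------------------------------------------------------------

def stack_slices(slices: list[tuple[np.ndarray, float]]) -> np.ndarray:
    """Stack (2D array, position) pairs ascending by position along axis 2."""
    if not slices:
        raise FormatError("no slices to stack")
    positions = [p for _, p in slices]
    if len(set(positions)) != len(positions):
        raise FormatError("duplicate slice positions")
    shapes = {s.shape for s, _ in slices}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent in-plane dims: {shapes}")
    ordered = sorted(slices, key=lambda sp: sp[1])
    return np.stack([s for s, _ in ordered], axis=2)


# ---------------------------------------------------------------------------
# DICOM reading
# ---------------------------------------------------------------------------

def _dcmread_retry(path: Path, retries: int = 3, delay: float = 0.05):
    """Read a DICOM file, retrying to tolerate partially written files."""
    last = None
    for attempt in range(retries + 1):
        try:
            ds = pydicom.dcmread(str(path))
            _ = ds.pixel_array  # force decode; raises while file is partial
            return ds
        except FileNotFoundError:
            raise
        except Exception as exc:  # pragma: no cover - timing dependent
            last = exc
            if attempt < retries:
                time.sleep(delay)
    raise FormatError(f"could not parse DICOM file {path}: {last}")


def _dicom_lps_frame(ds) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Row/column/normal direction cosines (LPS) and in-plane spacings."""
    iop = np.asarray([float(v) for v in ds.ImageOrientationPatient])
    col_dir = iop[:3]  # direction of increasing column index
    row_dir = iop[3:]  # direction of increasing row index
    normal = np.cross(col_dir, row_dir)
    ps = [float(v) for v in ds.PixelSpacing]  # (row spacing, col spacing)
    return row_dir, col_dir, normal, ps[0], ps[1]


def _dicom_native_affine(ds, slice_spacing: float) -> np.ndarray:
    """Native (row, col, slice)-indexed voxel->RAS world affine."""
    row_dir, col_dir, normal, dr, dc = _dicom_lps_frame(ds)
    ipp = np.asarray([float(v) for v in ds.ImagePositionPatient])
    aff = np.eye(4)
    aff[:3, 0] = row_dir * dr
    aff[:3, 1] = col_dir * dc
    aff[:3, 2] = normal * slice_spacing
    aff[:3, 3] = ipp
    # LPS (DICOM world) -> RAS world
    aff[0, :] *= -1.0
    aff[1, :] *= -1.0
    return aff


def _slice_spacing(ds) -> float:
    for tag in ("SpacingBetweenSlices", "SliceThickness"):
        if hasattr(ds, tag):
            return float(getattr(ds, tag))
    return 1.0


def read_dicom_slice(path: str | Path) -> dict:
    """Read one 2D slice DICOM; returns pixel data plus the tags we need."""
    ds = _dcmread_retry(Path(path))
    row_dir, col_dir, normal, _, _ = _dicom_lps_frame(ds)
    ipp = np.asarray([float(v) for v in ds.ImagePositionPatient])
    return {
        "pixels": ds.pixel_array,  # (rows, cols)
        "series": str(ds.SeriesNumber),
        "instance": int(ds.InstanceNumber),
        "slice_pos": float(np.dot(ipp, normal)),
        "n_slices": int(ds.ImagesInAcquisition) if hasattr(ds, "ImagesInAcquisition") else None,
        "n_timepts": int(ds.NumberOfTemporalPositions)
        if hasattr(ds, "NumberOfTemporalPositions")
        else None,
        "dataset": ds,
    }


def read_dicom_mosaic(path: str | Path, n_slices: int | None = None) -> dict:
    """Read one mosaic DICOM and de-tile it into a 3D stack."""
    ds = _dcmread_retry(Path(path))
    if MOSAIC_NSLICES_TAG in ds:
        n_slices = int(ds[MOSAIC_NSLICES_TAG].value)
    if n_slices is None:
        raise FormatError(f"mosaic {path} does not carry a slice count")
    g = infer_mosaic_grid(n_slices)
    mosaic = ds.pixel_array
    if mosaic.shape[0] % g or mosaic.shape[1] % g:
        raise FormatError(f"mosaic dims {mosaic.shape} not divisible by grid {g}")
    vol = demosaic(mosaic, mosaic.shape[0] // g, mosaic.shape[1] // g, n_slices)
    return {
        "volume": vol,
        "series": str(ds.SeriesNumber),
        "instance": int(ds.InstanceNumber),
        "n_slices": n_slices,
        "n_timepts": int(ds.NumberOfTemporalPositions)
        if hasattr(ds, "NumberOfTemporalPositions")
        else None,
        "dataset": ds,
    }


# ---------------------------------------------------------------------------
# PAR/REC
# ---------------------------------------------------------------------------

def read_parrec(par_path: str | Path, rec_path: str | Path | None = None):
    """Read a PAR/REC pair into a 4D array plus its geometry.

    Returns ``(data, geometry)`` where ``data`` has shape (x, y, z, t) in the
    header's native orientation (the caller reorients). A single-timepoint
    pair yields a final axis of length 1.
    """
    par_path = Path(par_path)
    if rec_path is None:
        for suffix in (".REC", ".rec"):
            cand = par_path.with_suffix(suffix)
            if cand.exists():
                rec_path = cand
                break
        else:
            raise FormatError(f"no REC file next to {par_path}")
    rec_path = Path(rec_path)
    try:
        img = nib_parrec.PARRECImage.from_filename(
            str(par_path), permit_truncated=False, scaling="dv"
        )
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"could not parse PAR/REC pair {par_path}: {exc}") from exc
    if data.ndim == 3:
        data = data[..., np.newaxis]
    hdr = img.header
    zooms = hdr.get_zooms()[:3]
    geom = VolumeGeometry(
        dims=data.shape[:3],
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine_ras=img.affine,
        expected_timepts=int(hdr.general_info.get("max_dynamics", data.shape[3])),
    )
    return data, geom


# ---------------------------------------------------------------------------
# assemblers: files in arrival order -> volumes in timepoint order
# ---------------------------------------------------------------------------

class _BaseAssembler:
    """Shared in-order emission logic.

    Completed volumes are buffered and released in strictly increasing
    ``vol_idx`` with no gaps, regardless of file arrival order.
    """

    def __init__(self) -> None:
        self.geometry: VolumeGeometry | None = None
        self._pending: dict[int, AssembledVolume] = {}
        self._next_emit = 0
        self._reorient: Reorientation | None = None

    def feed(self, raw: RawImageFile) -> list[AssembledVolume]:
        raise NotImplementedError

    def _finalize(self, vol_idx: int, native_data: np.ndarray, native_affine: np.ndarray,
                  expected_timepts: int | None) -> list[AssembledVolume]:
        if self._reorient is None:
            self._reorient, affine_ras = compute_ras_affine(
                native_affine, native_data.shape
            )
            data = self._reorient.apply(native_data)
            vox = tuple(
                float(v) for v in np.sqrt((affine_ras[:3, :3] ** 2).sum(axis=0))
            )
            self.geometry = VolumeGeometry(
                dims=data.shape,
                voxel_size_mm=vox,
                affine_ras=affine_ras,
                expected_timepts=expected_timepts,
            )
        else:
            data = self._reorient.apply(native_data)
        self._pending[vol_idx] = AssembledVolume(
            vol_idx=vol_idx, data=data, geometry=self.geometry
        )
        out = []
        while self._next_emit in self._pending:
            out.append(self._pending.pop(self._next_emit))
            self._next_emit += 1
        return out


class SliceAssembler(_BaseAssembler):
    """Per-slice 2D DICOM dialect (GE-style).

    Slices map to volumes in contiguous blocks of ``n_slices`` by instance
    number; a volume is assembled only once all of its slices are present.
    """

    def __init__(self, n_slices: int | None = None) -> None:
        super().__init__()
        self.n_slices = n_slices
        self._slices: dict[int, list[tuple[np.ndarray, float, int]]] = {}
        self._n_timepts: int | None = None
        self._affine_by_vol: dict[int, np.ndarray] = {}
        self._spacing: float | None = None
        self._done: set[int] = set()

    def feed(self, raw: RawImageFile) -> list[AssembledVolume]:
        try:
            info = read_dicom_slice(raw.path)
        except FileNotFoundError:
            log.warning("slice file vanished before read: %s", raw.path)
            return []
        if self.n_slices is None:
            self.n_slices = info["n_slices"]
        if self.n_slices is None:
            raise FormatError(
                "slice dialect needs n_slices (ImagesInAcquisition tag or config)"
            )
        if info["n_timepts"] is not None:
            self._n_timepts = info["n_timepts"]
        vol_idx = (info["instance"] - 1) // self.n_slices
        if vol_idx in self._done:
            log.error("slice for already-assembled volume %d ignored", vol_idx)
            return []
        bucket = self._slices.setdefault(vol_idx, [])
        if any(abs(info["slice_pos"] - p) < 1e-9 for _, p, _ in bucket):
            raise FormatError(
                f"duplicate slice position {info['slice_pos']} in volume {vol_idx}"
            )
        bucket.append((info["pixels"], info["slice_pos"], info["instance"]))
        if self._spacing is None:
            self._spacing = _slice_spacing(info["dataset"])
        # remember the affine anchored at the lowest slice of this volume
        lowest = min(bucket, key=lambda t: t[1])
        if lowest[2] == info["instance"]:
            self._affine_by_vol[vol_idx] = _dicom_native_affine(
                info["dataset"], self._spacing
            )
        if len(bucket) < self.n_slices:
            return []
        native = stack_slices([(px, pos) for px, pos, _ in bucket])
        aff = self._affine_by_vol.pop(vol_idx)
        del self._slices[vol_idx]
        self._done.add(vol_idx)
        return self._finalize(vol_idx, native, aff, self._n_timepts)


class MosaicAssembler(_BaseAssembler):
    """Per-volume mosaic DICOM dialect (Siemens-style)."""

    def __init__(self, n_slices: int | None = None) -> None:
        super().__init__()
        self.n_slices = n_slices

    def feed(self, raw: RawImageFile) -> list[AssembledVolume]:
        try:
            info = read_dicom_mosaic(raw.path, n_slices=self.n_slices)
        except FileNotFoundError:
            log.warning("mosaic file vanished before read: %s", raw.path)
            return []
        vol_idx = info["instance"] - 1
        spacing = _slice_spacing(info["dataset"])
        aff = _dicom_native_affine(info["dataset"], spacing)
        return self._finalize(vol_idx, info["volume"], aff, info["n_timepts"])


class ParRecAssembler(_BaseAssembler):
    """Per-timepoint PAR/REC pair dialect (Philips-style).

    A pair is read once both files exist; the trailing number in the stem
    gives the (1-based) timepoint.
    """

    _num_re = re.compile(r"(\d+)$")

    def __init__(self) -> None:
        super().__init__()
        self._seen_stems: dict[str, set[str]] = {}

    def feed(self, raw: RawImageFile) -> list[AssembledVolume]:
        path = Path(raw.path)
        suffix = path.suffix.lower()
        if suffix not in (".par", ".rec"):
            return []
        stem = str(path.with_suffix(""))
        have = self._seen_stems.setdefault(stem, set())
        have.add(suffix)
        if have != {".par", ".rec"}:
            return []
        par = _existing_case(path.with_suffix(""), ("PAR", "par"))
        try:
            data, _geom = read_parrec(par)
        except FormatError:
            raise
        m = self._num_re.search(path.stem)
        base_idx = (int(m.group(1)) - 1) if m else self._next_emit
        out: list[AssembledVolume] = []
        for t in range(data.shape[3]):
            out.extend(
                self._finalize(
                    base_idx + t, data[..., t], _geom.affine_ras, _geom.expected_timepts
                )
            )
        return out


def _existing_case(base: Path, exts: tuple[str, ...]) -> Path:
    for ext in exts:
        cand = base.with_suffix("." + ext)
        if cand.exists():
            return cand
    raise FileNotFoundError(base)


def make_assembler(dialect: str, n_slices: int | None = None) -> _BaseAssembler:
    if dialect == "slice2d":
        return SliceAssembler(n_slices=n_slices)
    if dialect == "mosaic":
        return MosaicAssembler(n_slices=n_slices)
    if dialect == "parrec":
        return ParRecAssembler()
    raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def assemble_files(
    files: Iterable[RawImageFile], dialect: str, n_slices: int | None = None
) -> Iterator[AssembledVolume]:
    """Assemble an ordered stream of raw files into in-order volumes."""
    asm = make_assembler(dialect, n_slices=n_slices)
    for raw in files:
        yield from asm.feed(raw)
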