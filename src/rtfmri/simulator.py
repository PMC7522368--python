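"""Scanner stand-ins: synthetic block-design runs, vendor-format fixture
writers, and the timed scanner/stream simulators.

The synthetic generator emulates a block-design hand-squeeze run:
alternating task/rest blocks (20 s each, five task blocks) with the BOLD
signal confined to supplied ROI masks as a percent change over baseline,
plus additive Gaussian noise. The scanner simulator re-emits a source
series into a watched directory one volume per TR; the stream simulator
bypasses files entirely and sends volumes straight over the socket.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import ConfigurationError, FormatError
from .geometry import VolumeGeometry
from .scanner_formats import MOSAIC_NSLICES_TAG, AssembledVolume, mosaicify
from .volume_stream import DEFAULT_HOST, SCANNER_PORT, VolumeSender

log = logging.getLogger(__name__)

__all__ = [
    "BlockDesign",
    "SyntheticSpec",
    "default_rois",
    "generate_synthetic_run",
    "write_fixture_series",
    "write_parrec_pair",
    "run_scanner_sim",
    "run_stream_sim",
    "DEFAULT_TR_MS",
    "DEFAULT_DIMS",
    "DEFAULT_NUM_TIMEPTS",
]

DEFAULT_TR_MS = 1000.0
DEFAULT_DIMS = (64, 64, 18)
DEFAULT_NUM_TIMEPTS = 60
DEFAULT_VOXEL_MM = (3.0, 3.0, 4.0)


@dataclass
class BlockDesign:
    """Alternating task/rest block design (defaults: 20 s blocks, 5 cycles)."""

    block_seconds: float = 20.0
    n_task_blocks: int = 5
    starts_with: str = "task"
    tr_ms: float = DEFAULT_TR_MS

    def __post_init__(self) -> None:
        if self.block_seconds <= 0 or self.n_task_blocks < 1:
            raise ConfigurationError("block design must have positive blocks")
        if self.starts_with not in ("task", "rest"):
            raise ConfigurationError("starts_with must be 'task' or 'rest'")
        ratio = self.block_seconds * 1000.0 / self.tr_ms
        if abs(ratio - round(ratio)) > 1e-6:
            raise ConfigurationError(
                f"block length {self.block_seconds}s is not a whole number of TRs"
            )

    @property
    def block_trs(self) -> int:
        return int(round(self.block_seconds * 1000.0 / self.tr_ms))

    def boxcar(self, num_timepts: int) -> np.ndarray:
        """On/off task regressor of length ``num_timepts``.

        The alternating design occupies the trailing timepoints; any
        remainder is leading rest (discarded steady-state style padding).
        """
        bt = self.block_trs
        first, second = (1, 0) if self.starts_with == "task" else (0, 1)
        cycle = np.array([first] * bt + [second] * bt, dtype=float)
        design = np.tile(cycle, self.n_task_blocks)
        pad = num_timepts - design.size
        if pad < 0:
            raise ConfigurationError(
                f"design of {design.size} timepoints does not fit num_timepts={num_timepts}"
            )
        return np.concatenate([np.zeros(pad), design])


def default_rois(dims: tuple[int, int, int] = DEFAULT_DIMS) -> dict[str, np.ndarray]:
    """Two built-in ROIs: a left-hemisphere 'motor' ellipsoid and a smaller,
    deeper 'caudate' ellipsoid, both well inside the volume."""
    nx, ny, nz = dims
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )

    def ellipsoid(cx, cy, cz, rx, ry, rz):
        return (
            ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
        ) <= 1.0

    motor = ellipsoid(0.30 * nx, 0.45 * ny, 0.70 * nz, 0.10 * nx, 0.12 * ny, 0.17 * nz)
    caudate = ellipsoid(0.40 * nx, 0.55 * ny, 0.45 * nz, 0.05 * nx, 0.07 * ny, 0.12 * nz)
    return {"motor": motor.astype(np.uint8), "caudate": caudate.astype(np.uint8)}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic run.

    Amplitudes and noise are percentages of baseline; the default 3%
    amplitude and 1% noise are typical of a robust motor block response.
    """

    dims: tuple[int, int, int] = DEFAULT_DIMS
    num_timepts: int = DEFAULT_NUM_TIMEPTS
    signal_rois: dict[str, tuple[np.ndarray, float]] | None = None
    noise_sd_pct: float = 1.0
    baseline: float = 1000.0
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_pct < 0:
            raise ConfigurationError("noise_sd_pct must be >= 0")
        if self.signal_rois is None:
            rois = default_rois(self.dims)
            self.signal_rois = {name: (m, 3.0) for name, m in rois.items()}
        for name, (m, amp) in self.signal_rois.items():
            if tuple(np.asarray(m).shape) != tuple(self.dims):
                raise ConfigurationError(f"ROI {name!r} does not fit dims {self.dims}")
            if amp < 0:
                raise ConfigurationError(f"ROI {name!r} amplitude must be >= 0")

    def geometry(self, expected_timepts: int | None = None) -> VolumeGeometry:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = -(np.asarray(self.dims) - 1) / 2.0 * self.voxel_size_mm
        return VolumeGeometry(
            dims=self.dims,
            voxel_size_mm=self.voxel_size_mm,
            affine_ras=aff,
            expected_timepts=expected_timepts or self.num_timepts,
        )


def generate_synthetic_run(
    spec: SyntheticSpec, design: BlockDesign | None = None, dtype=np.int16
):
    """Synthesize a block-design 4D run.

    Voxels inside each signal ROI follow ``baseline * (1 + amp% * boxcar(t))``
    plus Gaussian noise with SD ``noise_sd_pct%`` of baseline; all other
    voxels are baseline + noise. Integer dtypes are rounded (scanner files
    carry integer intensities); a fixed seed reproduces the run bit-exactly.

    Returns ``(data4d, boxcar, masks)`` where ``masks`` maps ROI name to its
    boolean mask.
    """
    if design is None:
        design = BlockDesign()
    boxcar = design.boxcar(spec.num_timepts)
    rng = np.random.default_rng(spec.seed)
    base = np.full(tuple(spec.dims) + (spec.num_timepts,), float(spec.baseline))
    for _name, (mask, amp_pct) in spec.signal_rois.items():
        sel = np.asarray(mask) > 0
        base[sel, :] += spec.baseline * (amp_pct / 100.0) * boxcar[np.newaxis, :]
    if spec.noise_sd_pct > 0:
        base += rng.normal(
            0.0, spec.baseline * spec.noise_sd_pct / 100.0, size=base.shape
        )
    if np.issubdtype(np.dtype(dtype), np.integer):
        data = np.rint(base).astype(dtype)
    else:
        data = base.astype(dtype)
    masks = {name: np.asarray(m) > 0 for name, (m, _a) in spec.signal_rois.items()}
    return data, boxcar, masks


def save_mask_nifti(mask: np.ndarray, path: str | Path, geometry: VolumeGeometry) -> Path:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), geometry.affine_ras)
    nib.save(img, str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# fixture writers (one per dialect)
# ---------------------------------------------------------------------------

def _lps_frame_from_ras(geometry: VolumeGeometry):
    """Decompose the RAS affine into DICOM (LPS) direction cosines/spacings.

    The stored slice order follows the DICOM cross-product normal, so the
    writer may reverse the slice axis; returns that flag too.
    """
    a_lps = geometry.affine_ras.copy()
    a_lps[0, :] *= -1.0
    a_lps[1, :] *= -1.0
    dr = float(np.linalg.norm(a_lps[:3, 0]))
    dc = float(np.linalg.norm(a_lps[:3, 1]))
    ds = float(np.linalg.norm(a_lps[:3, 2]))
    row_dir = a_lps[:3, 0] / dr
    col_dir = a_lps[:3, 1] / dc
    normal = np.cross(col_dir, row_dir)
    flip_slices = bool(np.dot(a_lps[:3, 2], normal) < 0)
    origin = a_lps[:3, 3].copy()
    if flip_slices:
        origin = origin + a_lps[:3, 2] * (geometry.dims[2] - 1)
    return row_dir, col_dir, normal, dr, dc, ds, origin, flip_slices


def _new_dicom(path: Path) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    return ds


def _set_pixels(ds: FileDataset, arr2d: np.ndarray) -> None:
    arr2d = np.ascontiguousarray(arr2d)
    if arr2d.dtype == np.int16:
        ds.PixelRepresentation = 1
    elif arr2d.dtype == np.uint16:
        ds.PixelRepresentation = 0
    else:
        raise FormatError(f"DICOM fixtures carry int16/uint16 pixels, not {arr2d.dtype}")
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = arr2d.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelData = arr2d.tobytes()


def _common_geometry_tags(ds, row_dir, col_dir, dr, dc, ds_mm, ipp) -> None:
    ds.ImageOrientationPatient = [f"{v:.8f}" for v in list(col_dir) + list(row_dir)]
    ds.ImagePositionPatient = [f"{v:.8f}" for v in ipp]
    ds.PixelSpacing = [f"{dr:.8f}", f"{dc:.8f}"]
    ds.SpacingBetweenSlices = f"{ds_mm:.8f}"
    ds.SliceThickness = f"{ds_mm:.8f}"


def write_fixture_series(
    vol4d: np.ndarray,
    dialect: str,
    out_dir: str | Path,
    geometry: VolumeGeometry | None = None,
    series: str = "000013",
) -> list[Path]:
    """Write a 4D array as one vendor-dialect file series.

    Files are returned in emission order (volume-major), named with the
    vendor's 1-based numbering, and are readable back by the
    :mod:`rtfmri.scanner_formats` assemblers.
    """
    vol4d = np.asarray(vol4d)
    if vol4d.ndim != 4:
        raise FormatError("fixture source must be 4D")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if geometry is None:
        geometry = VolumeGeometry(
            dims=vol4d.shape[:3],
            voxel_size_mm=DEFAULT_VOXEL_MM,
            expected_timepts=vol4d.shape[3],
        )
    nt = vol4d.shape[3]
    nz = vol4d.shape[2]
    paths: list[Path] = []

    if dialect in ("slice2d", "mosaic"):
        row_dir, col_dir, normal, dr, dc, ds_mm, origin, flip = _lps_frame_from_ras(
            geometry
        )
        slice_order = range(nz - 1, -1, -1) if flip else range(nz)
        for t in range(nt):
            stored = vol4d[:, :, list(slice_order), t]
            if dialect == "mosaic":
                path = out_dir / f"{series}_{t + 1:06d}.dcm"
                dcm = _new_dicom(path)
                _set_pixels(dcm, mosaicify(stored))
                _common_geometry_tags(dcm, row_dir, col_dir, dr, dc, ds_mm, origin)
                dcm.SeriesNumber = series
                dcm.InstanceNumber = t + 1
                dcm.NumberOfTemporalPositions = nt
                dcm.add_new(MOSAIC_NSLICES_TAG, "US", nz)
                dcm.save_as(str(path), enforce_file_format=True)
                paths.append(path)
            else:
                for z in range(nz):
                    instance = t * nz + z + 1
                    path = out_dir / f"{series}_{instance:06d}.dcm"
                    dcm = _new_dicom(path)
                    _set_pixels(dcm, stored[:, :, z])
                    ipp = origin + normal * ds_mm * z
                    _common_geometry_tags(dcm, row_dir, col_dir, dr, dc, ds_mm, ipp)
                    dcm.SeriesNumber = series
                    dcm.InstanceNumber = instance
                    dcm.ImagesInAcquisition = nz
                    dcm.NumberOfTemporalPositions = nt
                    dcm.save_as(str(path), enforce_file_format=True)
                    paths.append(path)
    elif dialect == "parrec":
        for t in range(nt):
            base = out_dir / f"{series}_{t + 1:04d}"
            par, rec = write_parrec_pair(vol4d[..., t : t + 1], base, geometry)
            paths.extend([par, rec])
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return paths


# ---------------------------------------------------------------------------
# PAR/REC writing
# ---------------------------------------------------------------------------

_PAR_HEADER = """\
# === DATA DESCRIPTION FILE ======================================================
#
# CAUTION - Investigational device.
#
# Dataset name: synthetic fixture series
#
# CLINICAL TRYOUT             Research image export tool     V4.2
#
# === GENERAL INFORMATION ========================================================
#
.    Patient name                       :   synthetic
.    Examination name                   :   fixture
.    Protocol name                      :   func
.    Examination date/time              :   2020.01.01 / 12:00:00
.    Series Type                        :   Image   MRSERIES
.    Acquisition nr                     :   1
.    Reconstruction nr                  :   1
.    Scan Duration [sec]                :   {nt}
.    Max. number of cardiac phases      :   1
.    Max. number of echoes              :   1
.    Max. number of slices/locations    :   {nz}
.    Max. number of dynamics            :   {nt}
.    Max. number of mixes               :   1
.    Patient position                   :   Head First Supine
.    Preparation direction              :   Anterior-Posterior
.    Technique                          :   FEEPI
.    Scan resolution  (x, y)            :   {nx}  {ny}
.    Scan mode                          :   MS
.    Repetition time [ms]               :   {tr:.3f}
.    FOV (ap,fh,rl) [mm]                :   {fov_ap:.3f}  {fov_fh:.3f}  {fov_rl:.3f}
.    Water Fat shift [pixels]           :   0.000
.    Angulation midslice(ap,fh,rl)[degr]:   0.000  0.000  0.000
.    Off Centre midslice(ap,fh,rl) [mm] :   0.000  0.000  0.000
.    Flow compensation <0=no 1=yes> ?   :   0
.    Presaturation     <0=no 1=yes> ?   :   0
.    Phase encoding velocity [cm/sec]   :   0.000000  0.000000  0.000000
.    MTC               <0=no 1=yes> ?   :   0
.    SPIR              <0=no 1=yes> ?   :   0
.    EPI factor        <0,1=no EPI>     :   1
.    Dynamic scan      <0=no 1=yes> ?   :   1
.    Diffusion         <0=no 1=yes> ?   :   0
.    Diffusion echo time [ms]           :   0.0000
.    Max. number of diffusion values    :   1
.    Max. number of gradient orients    :   1
.    Number of label types   <0=no ASL> :   0
#
# === PIXEL VALUES =============================================================
#  PV = pixel value in REC file, FP = floating point value, DV = displayed value on console
#  RS = rescale slope,           RI = rescale intercept,    SS = scale slope
#  DV = PV * RS + RI             FP = DV / (SS * RS)
#
# === IMAGE INFORMATION ==========================================================
#
"""


def write_parrec_pair(
    vol4d: np.ndarray,
    base_path: str | Path,
    geometry: VolumeGeometry | None = None,
    tr_ms: float = DEFAULT_TR_MS,
) -> tuple[Path, Path]:
    """Write a 4D array as one PAR/REC pair (V4.2-style text header + raw
    uint16 binary) readable back through nibabel.

    Rescale slope/intercept are written as 1/0 so voxel values pass through
    unchanged.
    """
    vol4d = np.asarray(vol4d)
    if vol4d.ndim == 3:
        vol4d = vol4d[..., np.newaxis]
    if vol4d.min() < 0 or vol4d.max() > np.iinfo(np.uint16).max:
        raise FormatError("PAR/REC fixture values must fit uint16")
    nx, ny, nz, nt = vol4d.shape
    if geometry is None:
        vox = DEFAULT_VOXEL_MM
    else:
        vox = geometry.voxel_size_mm
    base_path = Path(base_path)
    par_path = base_path.with_suffix(".PAR")
    rec_path = base_path.with_suffix(".REC")

    header = _PAR_HEADER.format(
        nx=nx, ny=ny, nz=nz, nt=nt, tr=tr_ms,
        fov_ap=ny * vox[1], fov_fh=nz * vox[2], fov_rl=nx * vox[0],
    )
    lines = []
    idx = 0
    for t in range(nt):
        for z in range(nz):
            zpos = (z - (nz - 1) / 2) * vox[2]
            lines.append(
                f"{z + 1:3d} 1 {t + 1:4d} 1 0 0 {idx:5d} 16 100 {nx} {ny} "
                f"0.000 1.000 1.000 500.0 1000.0 0.000 0.000 0.000 "
                f"0.000 {zpos:.3f} 0.000 {vox[2]:.3f} 0.000 0 1 0 2 "
                f"{vox[0]:.3f} {vox[1]:.3f} 30.0 0.0 0.0 0.0 1 90.0 0 0 0 0 "
                f"0.0 0 0 2 2 0.0 0.0 0.0 1"
            )
            idx += 1
    footer = "\n\n# === END OF DATA DESCRIPTION FILE ===============================================\n"
    with open(par_path, "w") as f:
        f.write(header + "\n".join(lines) + footer)
    with open(rec_path, "wb") as f:
        for t in range(nt):
            for z in range(nz):
                f.write(vol4d[:, :, z, t].astype("<u2").tobytes(order="F"))
    return par_path, rec_path


# ---------------------------------------------------------------------------
# timed simulators
# ---------------------------------------------------------------------------

def _detect_dialect(paths: list[Path]) -> str:
    exts = {p.suffix.lower() for p in paths}
    if {".par", ".rec"} & exts:
        return "parrec"
    if ".dcm" in exts:
        ds = pydicom.dcmread(str(next(p for p in paths if p.suffix.lower() == ".dcm")))
        return "mosaic" if MOSAIC_NSLICES_TAG in ds else "slice2d"
    raise ConfigurationError(f"cannot detect dialect from files: {sorted(exts)}")


def _group_by_volume(paths: list[Path], dialect: str) -> list[list[Path]]:
    """Group a series' files into per-volume emission batches."""
    if dialect == "mosaic":
        return [[p] for p in sorted(paths)]
    if dialect == "parrec":
        stems: dict[str, list[Path]] = {}
        for p in paths:
            stems.setdefault(p.stem, []).append(p)
        return [sorted(stems[s]) for s in sorted(stems)]
    # slice2d: contiguous blocks of n_slices by instance number
    ds = pydicom.dcmread(str(sorted(paths)[0]))
    n_slices = int(ds.ImagesInAcquisition)
    ordered = sorted(paths)
    if len(ordered) % n_slices:
        raise ConfigurationError(
            f"slice series has {len(ordered)} files, not a multiple of {n_slices}"
        )
    return [ordered[i : i + n_slices] for i in range(0, len(ordered), n_slices)]


def run_scanner_sim(
    source_dir: str | Path,
    series: str,
    tr_ms: float = DEFAULT_TR_MS,
    new_series: str | None = None,
    out_dir: str | Path | None = None,
) -> list[Path]:
    """Mimic a scanner: re-emit a source series one volume's files per TR.

    Files from ``source_dir`` whose names start with ``series`` are copied
    into ``out_dir`` (default: the source directory) under ``new_series``
    naming at a steady rate of one volume per TR. Returns the emitted paths;
    exactly as many files are emitted as the source series contains.
    """
    source_dir = Path(source_dir)
    out_dir = Path(out_dir) if out_dir is not None else source_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    new_series = new_series or series
    paths = [
        p for p in source_dir.iterdir()
        if p.is_file() and p.name.startswith(f"{series}_")
    ]
    if not paths:
        raise ConfigurationError(f"no files for series {series!r} in {source_dir}")
    dialect = _detect_dialect(paths)
    batches = _group_by_volume(paths, dialect)
    log.info(
        "Source dir: %s | volumes found: %d | TR: %g ms",
        source_dir, len(batches), tr_ms,
    )
    emitted: list[Path] = []
    interval = tr_ms / 1000.0
    next_t = time.monotonic()
    for batch in batches:
        lag = next_t - time.monotonic()
        if lag > 0:
            time.sleep(lag)
        next_t += interval
        for src in batch:
            dst = out_dir / src.name.replace(f"{series}_", f"{new_series}_", 1)
            dst.write_bytes(src.read_bytes())
            emitted.append(dst)
    return emitted


def run_stream_sim(
    source: str | Path | np.ndarray | None = None,
    dims: tuple[int, int, int, int] = DEFAULT_DIMS + (DEFAULT_NUM_TIMEPTS,),
    tr_ms: float = DEFAULT_TR_MS,
    host: str = DEFAULT_HOST,
    port: int = SCANNER_PORT,
    seed: int = 0,
) -> int:
    """Mimic the scanner-side process end to end: send volumes over the
    socket one per TR.

    ``source`` may be a 4D NIfTI path, a 4D array, or None for random data
    of the given dims. Blocks until the analysis side accepts the
    connection; returns the number of volumes sent.
    """
    if source is None:
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 2000, size=dims, dtype=np.int16)
        affine = np.diag(list(DEFAULT_VOXEL_MM) + [1.0])
    elif isinstance(source, (str, Path)):
        img = nib.load(str(source))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
        log.info("Prepping dataset: %s | Dimensions: %s | TR: %g", source, data.shape, tr_ms)
    else:
        data = np.asarray(source)
        affine = np.diag(list(DEFAULT_VOXEL_MM) + [1.0])
    if data.ndim != 4:
        raise ConfigurationError("stream source must be 4D")
    vox = tuple(float(v) for v in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    geom = VolumeGeometry(
        dims=data.shape[:3],
        voxel_size_mm=vox,
        affine_ras=affine,
        expected_timepts=data.shape[3],
    )
    interval = tr_ms / 1000.0
    sent = 0
    with VolumeSender(host=host, port=port) as sender:
        next_t = time.monotonic()
        for t in range(data.shape[3]):
            lag = next_t - time.monotonic()
            if lag > 0:
                time.sleep(lag)
            next_t += interval
            sender.send_volume(
                AssembledVolume(vol_idx=t, data=data[..., t], geometry=geom)
            )
            sent += 1
    return sent
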