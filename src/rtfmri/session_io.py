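"""Session configuration, mask handling, and run-output writing.

Masks are 3D NIfTI images, binary or weighted, and must match the spatial
dimensions of the incoming functional data (validated when the first volume
arrives). Run outputs land in an auto-incrementing ``pyneal_NNN`` directory
containing the received 4D data, a per-timepoint results document, motion
and timing series, and a plain-text log.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

from .errors import AnalysisError, ConfigurationError

log = logging.getLogger(__name__)

__all__ = [
    "Mask",
    "load_mask",
    "threshold_binarize",
    "make_whole_brain_mask",
    "load_scanner_config",
    "save_scanner_config",
    "load_session_config",
    "save_session_config",
    "next_run_dir",
    "write_run_output",
    "read_results_json",
    "SCANNER_CONFIG_KEYS",
]

SCANNER_CONFIG_KEYS = (
    "pynealSocketHost",
    "pynealSocketPort",
    "scannerBaseDir",
    "scannerMake",
)

_SESSION_DEFAULTS = {
    "pynealHost": "127.0.0.1",
    "pynealScannerPort": 5555,
    "resultsServerPort": 5558,
    "maskFile": None,
    "weightedMask": False,
    "numTimepts": 60,
    "analysisChoice": "average",
    "customAnalysisFile": None,
    "estimateMotion": True,
    "outputPath": "output",
    "trMs": 1000.0,
}


@dataclass
class Mask:
    """A 3D region-of-interest: binary or weighted, at least one positive voxel."""

    data: np.ndarray
    path: Path | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigurationError("mask must be a 3D image")
        if np.any(self.data < 0):
            raise ConfigurationError("mask values must be non-negative")
        if not np.any(self.data > 0):
            raise AnalysisError("mask has no positive voxels")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def weighted_capable(self) -> bool:
        vals = np.unique(self.data)
        return not np.all(np.isin(vals, (0, 1)))

    def check_dims(self, vol_dims) -> None:
        if tuple(vol_dims) != self.dims:
            raise ConfigurationError(
                f"mask dims {self.dims} do not match functional dims {tuple(vol_dims)}"
            )


def load_mask(path: str | Path) -> Mask:
    img = nib.load(str(path))
    return Mask(data=np.asanyarray(img.dataobj), path=Path(path))


def threshold_binarize(mask: np.ndarray, threshold: float) -> Mask:
    """Binarize on the native intensity scale: voxel = 1 iff value >= threshold."""
    arr = np.asarray(mask)
    out = (arr >= threshold).astype(np.uint8)
    if not out.any():
        raise AnalysisError(
            f"threshold {threshold} is above the mask maximum {arr.max()}: empty mask"
        )
    return Mask(data=out)


def make_whole_brain_mask(example_func: np.ndarray) -> Mask:
    """Intensity-threshold brain mask from one functional volume.

    Voxels above 10% of the robust (98th percentile) maximum are kept, the
    largest connected component is selected, and interior holes are filled.
    """
    vol = np.asarray(example_func, dtype=float)
    robust_max = np.percentile(vol, 98)
    rough = vol > 0.10 * robust_max
    if not rough.any():
        raise AnalysisError("no voxels above threshold; cannot build brain mask")
    labels, n = ndimage.label(rough)
    largest = np.argmax(ndimage.sum_labels(rough, labels, range(1, n + 1))) + 1
    filled = ndimage.binary_fill_holes(labels == largest)
    return Mask(data=filled.astype(np.uint8))


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

def load_scanner_config(path: str | Path) -> dict:
    """Read the scanner-side YAML config; all four keys are required.

    The parsed values are persisted back to the file so the last-used
    settings survive (matching the original last-used-settings behavior).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"scanner config not found: {path}")
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    for key in SCANNER_CONFIG_KEYS:
        if key not in cfg:
            raise ConfigurationError(f"scanner config missing required key: {key}")
    cfg["pynealSocketPort"] = int(cfg["pynealSocketPort"])
    save_scanner_config(path, cfg)
    return cfg


def save_scanner_config(path: str | Path, cfg: dict) -> None:
    out = {k: cfg[k] for k in SCANNER_CONFIG_KEYS}
    out["pynealSocketPort"] = str(out["pynealSocketPort"])
    with open(path, "w") as f:
        yaml.safe_dump(out, f, default_flow_style=False, sort_keys=False)


def load_session_config(path: str | Path) -> dict:
    """Read the analysis-side YAML config, filling defaults and persisting
    the resolved values back."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"session config not found: {path}")
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    merged = dict(_SESSION_DEFAULTS)
    merged.update(cfg)
    if merged["maskFile"] is None:
        raise ConfigurationError("session config missing required key: maskFile")
    if merged["analysisChoice"] == "custom" and not merged["customAnalysisFile"]:
        raise ConfigurationError(
            "analysisChoice 'custom' requires customAnalysisFile"
        )
    merged["numTimepts"] = int(merged["numTimepts"])
    merged["trMs"] = float(merged["trMs"])
    save_session_config(path, merged)
    return merged


def save_session_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, default_flow_style=False, sort_keys=False)


# ---------------------------------------------------------------------------
# run outputs
# ---------------------------------------------------------------------------

_RUN_DIR_RE = re.compile(r"^pyneal_(\d{3,})$")


def next_run_dir(output_root: str | Path) -> Path:
    """Create and return the next ``pyneal_NNN`` directory under the root.

    Numbering starts at 001 and increments past the highest existing run;
    creation is retried on collision so concurrent runs never share a dir.
    """
    root = Path(output_root)
    root.mkdir(parents=True, exist_ok=True)
    while True:
        existing = [
            int(m.group(1))
            for p in root.iterdir()
            if p.is_dir() and (m := _RUN_DIR_RE.match(p.name))
        ]
        nxt = (max(existing) + 1) if existing else 1
        candidate = root / f"pyneal_{nxt:03d}"
        try:
            candidate.mkdir()
            return candidate
        except FileExistsError:
            continue


def write_run_output(
    run_dir: str | Path,
    buffer_4d: np.ndarray,
    filled: np.ndarray,
    affine: np.ndarray,
    results: dict[int, dict],
    timings: list | None = None,
    motions: list | None = None,
) -> dict[str, Path]:
    """Write the received 4D NIfTI, results JSON, and motion/timing series.

    The NIfTI contains the buffer exactly as received (unfilled trailing
    timepoints trimmed); the results document has one object per processed
    timepoint keyed by its stringified volume index, nulls preserved.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    n_filled = int(np.max(np.nonzero(filled)[0])) + 1 if filled.any() else 0
    img = nib.Nifti1Image(buffer_4d[..., :n_filled], affine)
    func_path = run_dir / "receivedFunc.nii.gz"
    nib.save(img, str(func_path))
    out["received_func"] = func_path

    results_path = run_dir / "results.json"
    doc = {str(k): results[k] for k in sorted(results)}
    with open(results_path, "w") as f:
        json.dump(doc, f, indent=1)
    out["results_json"] = results_path

    if motions is not None:
        mpath = run_dir / "motion.tsv"
        with open(mpath, "w") as f:
            f.write("vol_idx\tabs_disp_mm\trel_disp_mm\n")
            for m in motions:
                f.write(f"{m.vol_idx}\t{m.abs_disp_mm:.6f}\t{m.rel_disp_mm:.6f}\n")
        out["motion"] = mpath
    if timings is not None:
        tpath = run_dir / "timing.tsv"
        with open(tpath, "w") as f:
            f.write("vol_idx\tprocessing_seconds\n")
            for t in timings:
                f.write(f"{t.vol_idx}\t{t.processing_seconds:.6f}\n")
        out["timing"] = tpath
    return out


def read_results_json(path: str | Path) -> dict[int, dict]:
    with open(path) as f:
        doc = json.load(f)
    return {int(k): v for k, v in doc.items()}
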