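"""The analysis-side engine: buffer, motion-check, analyze, record, serve.

Volumes arrive one per TR over the volume stream. Each one is placed at its
timepoint in a preallocated 4D buffer, optionally motion-checked against the
run's reference volume and the previous volume, pushed through the
configured analysis (built-in ROI mean/median or a user plugin), and its
result recorded under its 0-based volume index where the results server can
hand it to remote clients.

Analyses receive the raw (uncorrected) volume; motion is estimated and
reported alongside, never applied.
"""

from __future__ import annotations

import importlib.util
import logging
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AnalysisError, ConfigurationError, ProtocolError
from .geometry import VolumeGeometry
from .motion import MotionEstimate, estimate_motion
from .results_service import ResultsServer, ResultsStore
from .scanner_formats import AssembledVolume
from .session_io import Mask, load_mask, next_run_dir, write_run_output
from .volume_stream import DEFAULT_HOST, SCANNER_PORT, VolumeReceiver

log = logging.getLogger(__name__)

__all__ = [
    "ScanSession",
    "Timeseries4D",
    "TimingRecord",
    "ingest",
    "mean_roi",
    "median_roi",
    "load_plugin",
    "plugin_compute",
    "RealtimeEngine",
]

ANALYSIS_CHOICES = ("average", "median", "custom")


@dataclass
class ScanSession:
    """Everything the engine needs to know about one scan (run)."""

    num_timepts: int
    mask: Mask
    weighted: bool = False
    analysis_choice: str = "average"
    custom_analysis: object | None = None  # script path or ready plugin handle
    estimate_motion: bool = True
    output_dir: str | Path = "output"
    tr_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.num_timepts < 1:
            raise ConfigurationError("numTimepts must be >= 1")
        if self.analysis_choice not in ANALYSIS_CHOICES:
            raise ConfigurationError(
                f"analysisChoice must be one of {ANALYSIS_CHOICES}"
            )
        if self.analysis_choice == "median" and self.weighted:
            raise ConfigurationError("median analysis does not support weighting")
        if self.analysis_choice == "custom" and self.custom_analysis is None:
            raise ConfigurationError("custom analysis requires a script or handle")


@dataclass
class Timeseries4D:
    """Preallocated 4D buffer that fills in incrementally during the scan."""

    dims: tuple[int, int, int]
    num_timepts: int
    dtype: np.dtype = np.dtype(np.float64)
    buffer: np.ndarray = field(init=False)
    filled: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.buffer = np.zeros(tuple(self.dims) + (self.num_timepts,), dtype=self.dtype)
        self.filled = np.zeros(self.num_timepts, dtype=bool)

    @property
    def n_filled(self) -> int:
        return int(self.filled.sum())


@dataclass(frozen=True)
class TimingRecord:
    vol_idx: int
    processing_seconds: float


def ingest(v: AssembledVolume, ts: Timeseries4D) -> Timeseries4D:
    """Place one volume at its timepoint in the buffer (first write wins)."""
    if not (0 <= v.vol_idx < ts.num_timepts):
        raise ProtocolError(
            f"volume index {v.vol_idx} outside [0, {ts.num_timepts})"
        )
    if ts.filled[v.vol_idx]:
        log.error("duplicate volume index %d ignored (first write wins)", v.vol_idx)
        return ts
    ts.buffer[..., v.vol_idx] = v.data
    ts.filled[v.vol_idx] = True
    return ts


# ---------------------------------------------------------------------------
# built-in ROI statistics
# ---------------------------------------------------------------------------

def mean_roi(v: np.ndarray, mask: Mask, weighted: bool = False) -> float:
    """Mean signal within the mask; weighted by mask values if requested."""
    mask.check_dims(v.shape)
    w = mask.data
    sel = w > 0
    if not sel.any():
        raise AnalysisError("mask has no positive voxels")
    vals = np.asarray(v, dtype=np.float64)[sel]
    if weighted:
        wv = np.asarray(w, dtype=np.float64)[sel]
        return float((wv * vals).sum() / wv.sum())
    return float(vals.mean())


def median_roi(v: np.ndarray, mask: Mask) -> float:
    """Median signal over voxels with positive mask value (even counts
    average the central pair)."""
    mask.check_dims(v.shape)
    sel = mask.data > 0
    if not sel.any():
        raise AnalysisError("mask has no positive voxels")
    return float(np.median(np.asarray(v, dtype=np.float64)[sel]))


# ---------------------------------------------------------------------------
# custom analysis plugins
# ---------------------------------------------------------------------------

def load_plugin(
    script: str | Path, mask: Mask, num_timepts: int, tr_ms: float
):
    """Load a user analysis script and instantiate its entry point.

    The script must define a class ``CustomAnalysis`` accepting keyword
    arguments ``mask`` (the session :class:`Mask`), ``num_timepts``, and
    ``tr_ms``, with a ``compute(vol, vol_idx) -> dict`` method. Both entry
    points are validated here, at setup, so a malformed script fails before
    the scan rather than during it. State set in ``__init__`` persists
    across ``compute`` calls.
    """
    script = Path(script)
    if not script.exists():
        raise ConfigurationError(f"custom analysis script not found: {script}")
    spec = importlib.util.spec_from_file_location(f"rtfmri_plugin_{script.stem}", script)
    module = importlib.util.module_from_spec(spec)
    try:
        spec.loader.exec_module(module)
    except Exception as exc:
        raise ConfigurationError(f"custom analysis script failed to import: {exc}") from exc
    cls = getattr(module, "CustomAnalysis", None)
    if cls is None:
        raise ConfigurationError(
            f"{script} does not define the required CustomAnalysis class"
        )
    if not callable(getattr(cls, "compute", None)):
        raise ConfigurationError(
            f"{script}: CustomAnalysis has no compute(vol, vol_idx) method"
        )
    try:
        return cls(mask=mask, num_timepts=num_timepts, tr_ms=tr_ms)
    except Exception as exc:
        raise ConfigurationError(f"CustomAnalysis initialization failed: {exc}") from exc


def plugin_compute(handle, v: np.ndarray, vol_idx: int) -> dict:
    """Run one plugin compute call; failures are logged, never fatal."""
    try:
        result = handle.compute(v, vol_idx)
    except Exception:
        log.exception("custom analysis failed on volume %d; recording empty result", vol_idx)
        return {}
    if result is None:
        return {}
    if not isinstance(result, dict):
        log.error(
            "custom analysis returned %r (expected dict) on volume %d",
            type(result).__name__, vol_idx,
        )
        return {}
    return result


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

class RealtimeEngine:
    """Drives one scan: ingest -> motion -> analysis -> results store.

    Can be fed volumes directly (:meth:`process_volume`) or run as the
    network service (:meth:`run`) that listens for the scanner stream and
    serves results to remote clients.
    """

    def __init__(self, session: ScanSession) -> None:
        self.session = session
        self.store = ResultsStore()
        self.timeseries: Timeseries4D | None = None
        self.geometry: VolumeGeometry | None = None
        self.motions: list[MotionEstimate] = []
        self.timings: list[TimingRecord] = []
        self._ref: np.ndarray | None = None
        self._prev: np.ndarray | None = None
        self._plugin = None
        if session.analysis_choice == "custom":
            handle = session.custom_analysis
            if isinstance(handle, (str, Path)):
                handle = load_plugin(
                    handle, session.mask, session.num_timepts, session.tr_ms
                )
            if not callable(getattr(handle, "compute", None)):
                raise ConfigurationError("custom analysis handle has no compute method")
            self._plugin = handle

    # -- per-volume path ----------------------------------------------------

    def process_volume(self, v: AssembledVolume) -> dict:
        """Full per-volume pipeline; returns the recorded result mapping."""
        t0 = time.perf_counter()
        if self.timeseries is None:
            self.session.mask.check_dims(v.data.shape)
            self.geometry = v.geometry
            self.timeseries = Timeseries4D(
                dims=tuple(v.data.shape),
                num_timepts=self.session.num_timepts,
                dtype=v.data.dtype,
            )
        ingest(v, self.timeseries)

        vol = np.asarray(v.data, dtype=np.float64)
        if self.session.estimate_motion:
            if self._ref is None:
                self._ref = vol
            m = estimate_motion(
                vol, self._ref, self._prev if self._prev is not None else self._ref,
                self.geometry, vol_idx=v.vol_idx,
            )
            if v.vol_idx == 0:
                m = MotionEstimate(vol_idx=0, abs_disp_mm=m.abs_disp_mm, rel_disp_mm=0.0)
            self.motions.append(m)
            self._prev = vol

        if self.session.analysis_choice == "average":
            values = {"average": mean_roi(vol, self.session.mask, self.session.weighted)}
        elif self.session.analysis_choice == "median":
            values = {"median": median_roi(vol, self.session.mask)}
        else:
            values = plugin_compute(self._plugin, vol, v.vol_idx)

        self.store.update(v.vol_idx, values)
        elapsed = time.perf_counter() - t0
        self.timings.append(TimingRecord(vol_idx=v.vol_idx, processing_seconds=elapsed))
        log.info(
            "vol %d processed in %.1f ms: %s", v.vol_idx, elapsed * 1e3, values
        )
        return values

    # -- network service ----------------------------------------------------

    def run(
        self,
        host: str = DEFAULT_HOST,
        scanner_port: int = SCANNER_PORT,
        results_port: int | None = None,
        accept_timeout: float | None = None,
        write_outputs: bool = True,
    ):
        """Listen for the scanner stream, process every volume, write outputs.

        Returns the run directory (or None when ``write_outputs`` is False).
        Ends when ``num_timepts`` volumes have been processed or the sender
        disconnects; volumes already received are always kept.
        """
        results_server = None
        receiver = VolumeReceiver(host=host, port=scanner_port)
        self.bound_scanner_port = receiver.port
        if results_port is not None:
            results_server = ResultsServer(self.store, host=host, port=results_port)
            results_server.start()
            self.bound_results_port = results_server.port
        try:
            receiver.accept(timeout=accept_timeout)
            while self.timeseries is None or self.timeseries.n_filled < self.session.num_timepts:
                try:
                    vol = receiver.receive_volume()
                except ProtocolError as exc:
                    log.error("protocol error on stream: %s", exc)
                    break
                if vol is None:
                    log.error("scanner stream disconnected; keeping received volumes")
                    break
                self.process_volume(vol)
        finally:
            receiver.close()
            if results_server is not None:
                results_server.stop()
        if write_outputs:
            return self.write_outputs()
        return None

    def write_outputs(self) -> Path:
        """Write receivedFunc / results / motion / timing / log to a fresh
        ``pyneal_NNN`` run directory."""
        run_dir = next_run_dir(self.session.output_dir)
        if self.timeseries is None:
            buffer = np.zeros((1, 1, 1, 0))
            filled = np.zeros(0, dtype=bool)
            affine = np.eye(4)
        else:
            buffer = self.timeseries.buffer
            filled = self.timeseries.filled
            affine = self.geometry.affine_ras
        write_run_output(
            run_dir,
            buffer,
            filled,
            affine,
            self.store.as_dict(),
            timings=self.timings,
            motions=self.motions if self.session.estimate_motion else None,
        )
        with open(run_dir / "pynealLog.log", "w") as f:
            f.write(self._log_text())
        return run_dir

    def _log_text(self) -> str:
        s = self.session
        lines = [
            "scan session settings:",
            f"  numTimepts: {s.num_timepts}",
            f"  analysisChoice: {s.analysis_choice}",
            f"  weightedMask: {s.weighted}",
            f"  estimateMotion: {s.estimate_motion}",
            f"  trMs: {s.tr_ms}",
            f"  maskFile: {s.mask.path}",
        ]
        for t in self.timings:
            lines.append(
                f"vol {t.vol_idx}: processed in {t.processing_seconds * 1e3:.1f} ms"
            )
        for m in self.motions:
            lines.append(
                f"vol {m.vol_idx}: motion abs {m.abs_disp_mm:.4f} mm, "
                f"rel {m.rel_disp_mm:.4f} mm"
            )
        return "\n".join(lines) + "\n"


def session_from_config(cfg: dict) -> ScanSession:
    """Build a ScanSession from a parsed session config mapping."""
    mask = load_mask(cfg["maskFile"])
    return ScanSession(
        num_timepts=int(cfg["numTimepts"]),
        mask=mask,
        weighted=bool(cfg.get("weightedMask", False)),
        analysis_choice=cfg.get("analysisChoice", "average"),
        custom_analysis=cfg.get("customAnalysisFile"),
        estimate_motion=bool(cfg.get("estimateMotion", True)),
        output_dir=cfg.get("outputPath", "output"),
        tr_ms=float(cfg.get("trMs", 1000.0)),
    )
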