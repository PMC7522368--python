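"""Scanner-side pipeline: watch a directory, assemble volumes, stream them.

This is the process that runs at (or with filesystem access to) the scanner
console. It polls the export directory for new files in the configured
vendor dialect, assembles complete 3D volumes in timepoint order, reorients
them to RAS+, and pushes each one to the analysis side over the volume
stream as soon as it is complete.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .errors import ConfigurationError
from .scanner_formats import make_assembler, watch_directory
from .volume_stream import VolumeSender

log = logging.getLogger(__name__)

__all__ = ["MAKE_TO_DIALECT", "run_scanner_pipeline"]

MAKE_TO_DIALECT = {
    "ge": "slice2d",
    "siemens": "mosaic",
    "philips": "parrec",
}


def dialect_for_make(scanner_make: str) -> str:
    try:
        return MAKE_TO_DIALECT[scanner_make.strip().lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown scannerMake {scanner_make!r}; expected GE, Siemens, or Philips"
        ) from None


def run_scanner_pipeline(
    watch_dir: str | Path,
    dialect: str,
    host: str,
    port: int,
    poll_interval: float = 0.05,
    n_slices: int | None = None,
    expected_volumes: int | None = None,
    stop_event=None,
    timeout: float | None = None,
    ready_event=None,
) -> int:
    """Watch, assemble, and stream until the run ends.

    The run ends when ``expected_volumes`` volumes have been sent, the
    ``stop_event`` is set, or ``timeout`` seconds pass without completion.
    Returns the number of volumes streamed.
    """
    watch_dir = Path(watch_dir)
    if not watch_dir.is_dir():
        raise ConfigurationError(f"scanner directory does not exist: {watch_dir}")
    assembler = make_assembler(dialect, n_slices=n_slices)
    sent = 0
    with VolumeSender(host=host, port=port) as sender:
        for raw in watch_directory(
            watch_dir, poll_interval=poll_interval, dialect=dialect,
            stop_event=stop_event, timeout=timeout, ready_event=ready_event,
        ):
            for vol in assembler.feed(raw):
                sender.send_volume(vol)
                sent += 1
                log.info("streamed volume %d", vol.vol_idx)
            expected = expected_volumes
            if expected is None and assembler.geometry is not None:
                expected = assembler.geometry.expected_timepts
            if expected is not None and sent >= expected:
                break
    return sent
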