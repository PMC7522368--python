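import threading

import numpy as np
import pytest

from rtfmri.geometry import VolumeGeometry
from rtfmri.realtime_engine import RealtimeEngine
from rtfmri.scanner_formats import AssembledVolume, RawImageFile


@pytest.fixture
def rng():
    return np.random.default_rng(20200915)


@pytest.fixture
def small_geometry():
    aff = np.diag([3.0, 3.0, 4.0, 1.0])
    aff[:3, 3] = [-22.5, -22.5, -10.0]
    return VolumeGeometry(
        dims=(16, 16, 6), voxel_size_mm=(3.0, 3.0, 4.0), affine_ras=aff
    )


def make_volume(data, vol_idx=0, voxel_size=(3.0, 3.0, 4.0), expected_timepts=None):
    geom = VolumeGeometry(
        dims=data.shape, voxel_size_mm=voxel_size, expected_timepts=expected_timepts
    )
    return AssembledVolume(vol_idx=vol_idx, data=data, geometry=geom)


def as_raw_files(paths, dialect):
    return [
        RawImageFile(path=p, series_id="fix", arrival_order=i, dialect=dialect)
        for i, p in enumerate(paths)
    ]


def run_engine_in_thread(engine: RealtimeEngine, **kwargs):
    """Start engine.run in a thread; returns (thread, result-holder dict).

    Blocks until the scanner port is bound so the caller can connect.
    """
    holder = {}

    def target():
        holder["run_dir"] = engine.run(scanner_port=0, results_port=0, **kwargs)

    t = threading.Thread(target=target, daemon=True)
    t.start()
    while not hasattr(engine, "bound_results_port"):
        pass
    holder["scanner_port"] = engine.bound_scanner_port
    holder["results_port"] = engine.bound_results_port
    return t, holder
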