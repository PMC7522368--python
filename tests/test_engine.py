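"""Buffer ingestion, built-in ROI statistics, and the plugin contract."""

import numpy as np
import pytest

from rtfmri.errors import AnalysisError, ConfigurationError, ProtocolError
from rtfmri.realtime_engine import (
    RealtimeEngine,
    ScanSession,
    Timeseries4D,
    ingest,
    load_plugin,
    mean_roi,
    median_roi,
    plugin_compute,
)
from rtfmri.session_io import Mask

from conftest import make_volume


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def test_first_volume_fills_its_slot(rng):
    ts = Timeseries4D(dims=(4, 4, 2), num_timepts=3, dtype=np.dtype(np.int16))
    data = rng.integers(0, 99, size=(4, 4, 2)).astype(np.int16)
    ingest(make_volume(data, vol_idx=0), ts)
    assert ts.filled.tolist() == [True, False, False]
    assert np.array_equal(ts.buffer[..., 0], data)


def test_ingest_all_timepoints_reproduces_source(rng):
    data4d = rng.integers(0, 99, size=(4, 4, 2, 6)).astype(np.int16)
    ts = Timeseries4D(dims=(4, 4, 2), num_timepts=6, dtype=np.dtype(np.int16))
    for t in range(6):
        ingest(make_volume(data4d[..., t], vol_idx=t), ts)
    assert ts.n_filled == 6
    assert np.array_equal(ts.buffer, data4d)


def test_duplicate_index_first_write_wins(rng, caplog):
    ts = Timeseries4D(dims=(2, 2, 2), num_timepts=8, dtype=np.dtype(np.int16))
    first = rng.integers(0, 99, size=(2, 2, 2)).astype(np.int16)
    second = first + 1
    ingest(make_volume(first, vol_idx=5), ts)
    with caplog.at_level("ERROR"):
        ingest(make_volume(second, vol_idx=5), ts)
    assert "duplicate" in caplog.text
    assert np.array_equal(ts.buffer[..., 5], first)


def test_out_of_range_index_is_protocol_error(rng):
    ts = Timeseries4D(dims=(2, 2, 2), num_timepts=3, dtype=np.dtype(np.int16))
    with pytest.raises(ProtocolError):
        ingest(make_volume(np.zeros((2, 2, 2), dtype=np.int16), vol_idx=3), ts)


# ---------------------------------------------------------------------------
# built-in ROI statistics
# ---------------------------------------------------------------------------

def test_mean_of_constant_volume_is_the_constant():
    mask = Mask(data=np.ones((3, 3, 3)))
    vol = np.full((3, 3, 3), 42.5)
    assert mean_roi(vol, mask) == 42.5
    assert mean_roi(vol, mask, weighted=True) == 42.5


def test_weighted_mean_matches_hand_computation():
    # values (1, 2, 3) with weights (1, 1, 2) -> (1 + 2 + 6) / 4 = 2.25
    vol = np.zeros((3, 1, 1))
    vol[:, 0, 0] = [1.0, 2.0, 3.0]
    w = np.zeros((3, 1, 1))
    w[:, 0, 0] = [1.0, 1.0, 2.0]
    assert mean_roi(vol, Mask(data=w), weighted=True) == pytest.approx(2.25, abs=0)


def test_single_voxel_median_is_that_voxel(rng):
    vol = rng.normal(size=(4, 4, 4))
    m = np.zeros((4, 4, 4))
    m[1, 2, 3] = 1
    assert median_roi(vol, Mask(data=m)) == vol[1, 2, 3]


def test_even_count_median_averages_central_pair():
    vol = np.zeros((4, 1, 1))
    vol[:, 0, 0] = [1.0, 2.0, 3.0, 4.0]
    assert median_roi(vol, Mask(data=np.ones((4, 1, 1)))) == 2.5


def test_roi_statistics_match_bruteforce_oracle(rng):
    """Mean, weighted mean, and median against explicit voxel loops,
    100 random instances, 1e-10 relative."""
    for _ in range(100):
        vol = rng.normal(loc=1000, scale=50, size=(6, 5, 4))
        w = rng.uniform(0, 2, size=(6, 5, 4)) * (rng.random((6, 5, 4)) < 0.5)
        if not (w > 0).any():
            w[0, 0, 0] = 1.0
        mask = Mask(data=w)
        num = den = 0.0
        vals = []
        for i in range(6):
            for j in range(5):
                for k in range(4):
                    if w[i, j, k] > 0:
                        vals.append(vol[i, j, k])
                        num += w[i, j, k] * vol[i, j, k]
                        den += w[i, j, k]
        assert mean_roi(vol, mask) == pytest.approx(np.mean(vals), rel=1e-10)
        assert mean_roi(vol, mask, weighted=True) == pytest.approx(num / den, rel=1e-10)
        srt = sorted(vals)
        n = len(srt)
        med = srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
        assert median_roi(vol, mask) == pytest.approx(med, rel=1e-10)


def test_empty_mask_is_analysis_error():
    with pytest.raises(AnalysisError):
        Mask(data=np.zeros((2, 2, 2)))


def test_median_with_weighting_is_configuration_error():
    mask = Mask(data=np.ones((2, 2, 2)))
    with pytest.raises(ConfigurationError):
        ScanSession(num_timepts=5, mask=mask, analysis_choice="median", weighted=True)


# ---------------------------------------------------------------------------
# plugin contract
# ---------------------------------------------------------------------------

PLUGIN_OK = """
import numpy as np

class CustomAnalysis:
    def __init__(self, mask, num_timepts, tr_ms, **kw):
        self.mask = mask.data > 0
        self.calls = []

    def compute(self, vol, vol_idx):
        self.calls.append(vol_idx)
        return {"average": float(np.mean(vol[self.mask]))}
"""

PLUGIN_NO_COMPUTE = """
class CustomAnalysis:
    def __init__(self, mask, num_timepts, tr_ms, **kw):
        pass
"""

PLUGIN_RAISES = """
class CustomAnalysis:
    def __init__(self, mask, num_timepts, tr_ms, **kw):
        pass

    def compute(self, vol, vol_idx):
        raise RuntimeError("deliberate plugin failure")
"""


def _mask():
    m = np.zeros((4, 4, 2))
    m[1:3, 1:3, :] = 1
    return Mask(data=m)


def test_plugin_initializer_runs_once_and_state_persists(tmp_path, rng):
    script = tmp_path / "plug.py"
    script.write_text(PLUGIN_OK)
    handle = load_plugin(script, _mask(), num_timepts=5, tr_ms=1000.0)
    for i in range(3):
        out = plugin_compute(handle, rng.normal(size=(4, 4, 2)), i)
        assert set(out) == {"average"}
    assert handle.calls == [0, 1, 2]


def test_plugin_missing_compute_fails_at_setup(tmp_path):
    script = tmp_path / "bad.py"
    script.write_text(PLUGIN_NO_COMPUTE)
    with pytest.raises(ConfigurationError):
        load_plugin(script, _mask(), num_timepts=5, tr_ms=1000.0)


def test_plugin_exception_yields_empty_result_and_scan_continues(tmp_path, rng, caplog):
    script = tmp_path / "raises.py"
    script.write_text(PLUGIN_RAISES)
    session = ScanSession(
        num_timepts=3, mask=_mask(), analysis_choice="custom",
        custom_analysis=script, estimate_motion=False, output_dir=tmp_path / "out",
    )
    engine = RealtimeEngine(session)
    with caplog.at_level("ERROR"):
        for t in range(3):
            data = rng.integers(0, 99, size=(4, 4, 2)).astype(np.int16)
            out = engine.process_volume(make_volume(data, vol_idx=t))
            assert out == {}
    assert "custom analysis failed" in caplog.text
    assert len(engine.store) == 3  # every volume still has a result entry


# ---------------------------------------------------------------------------
# per-volume bookkeeping
# ---------------------------------------------------------------------------

def test_every_volume_yields_one_result_and_one_timing(rng, tmp_path):
    session = ScanSession(
        num_timepts=7, mask=_mask(), analysis_choice="average",
        estimate_motion=False, output_dir=tmp_path,
    )
    engine = RealtimeEngine(session)
    for t in range(7):
        data = rng.integers(0, 999, size=(4, 4, 2)).astype(np.int16)
        engine.process_volume(make_volume(data, vol_idx=t))
    assert len(engine.store) == 7
    assert [t.vol_idx for t in engine.timings] == list(range(7))
    assert all(t.processing_seconds >= 0 for t in engine.timings)


def test_mask_dims_validated_at_first_volume(rng, tmp_path):
    session = ScanSession(
        num_timepts=2, mask=_mask(), analysis_choice="average",
        estimate_motion=False, output_dir=tmp_path,
    )
    engine = RealtimeEngine(session)
    wrong = rng.integers(0, 9, size=(5, 5, 3)).astype(np.int16)
    with pytest.raises(ConfigurationError):
        engine.process_volume(make_volume(wrong, vol_idx=0))


def test_repeat_runs_are_deterministic(rng, tmp_path):
    """Identical input volumes with identical config give byte-identical
    results documents."""
    data4d = rng.integers(0, 2000, size=(8, 8, 4, 10)).astype(np.int16)
    m = np.zeros((8, 8, 4))
    m[2:6, 2:6, 1:3] = 1
    docs = []
    for run in range(2):
        session = ScanSession(
            num_timepts=10, mask=Mask(data=m), analysis_choice="average",
            estimate_motion=True, output_dir=tmp_path / f"run{run}",
        )
        engine = RealtimeEngine(session)
        for t in range(10):
            engine.process_volume(make_volume(data4d[..., t], vol_idx=t))
        run_dir = engine.write_outputs()
        docs.append((run_dir / "results.json").read_bytes())
    assert docs[0] == docs[1]
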