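"""Synthetic block-design generation and the timed simulators."""

import threading

import numpy as np
import pytest

from rtfmri.errors import ConfigurationError
from rtfmri.realtime_engine import RealtimeEngine, ScanSession
from rtfmri.scanner_formats import assemble_files
from rtfmri.session_io import Mask
from rtfmri.simulator import (
    BlockDesign,
    SyntheticSpec,
    default_rois,
    generate_synthetic_run,
    run_scanner_sim,
    run_stream_sim,
    write_fixture_series,
)

from conftest import as_raw_files, run_engine_in_thread


# ---------------------------------------------------------------------------
# block design
# ---------------------------------------------------------------------------

def test_boxcar_alternates_task_and_rest():
    design = BlockDesign(block_seconds=20.0, n_task_blocks=5, tr_ms=1000.0)
    box = design.boxcar(200)
    assert box.size == 200
    assert box[:20].tolist() == [1.0] * 20
    assert box[20:40].tolist() == [0.0] * 20
    assert box.sum() == 5 * 20


def test_remainder_becomes_leading_rest():
    design = BlockDesign(block_seconds=20.0, n_task_blocks=5, tr_ms=1000.0)
    box = design.boxcar(208)
    assert box[:8].tolist() == [0.0] * 8
    assert box[8:28].tolist() == [1.0] * 20


def test_design_longer_than_run_is_configuration_error():
    design = BlockDesign(block_seconds=20.0, n_task_blocks=5, tr_ms=1000.0)
    with pytest.raises(ConfigurationError):
        design.boxcar(60)


def test_block_length_must_be_whole_trs():
    with pytest.raises(ConfigurationError):
        BlockDesign(block_seconds=1.5, tr_ms=1000.0)


# ---------------------------------------------------------------------------
# synthetic runs
# ---------------------------------------------------------------------------

def _small_spec(noise, amp, nt=12, seed=3):
    rois = default_rois((16, 16, 6))
    return SyntheticSpec(
        dims=(16, 16, 6), num_timepts=nt, noise_sd_pct=noise, seed=seed,
        signal_rois={k: (v, amp) for k, v in rois.items()},
    )


_DESIGN = BlockDesign(block_seconds=2.0, n_task_blocks=3, tr_ms=1000.0)
_TINY_DESIGN = BlockDesign(block_seconds=1.0, n_task_blocks=1, tr_ms=1000.0)


def test_zero_amplitude_zero_noise_is_constant():
    data, _, _ = generate_synthetic_run(_small_spec(0.0, 0.0), _DESIGN)
    assert np.ptp(data) == 0
    assert data.flat[0] == 1000


def test_noiseless_roi_mean_is_exactly_the_scaled_boxcar():
    spec = _small_spec(0.0, 3.0)
    data, boxcar, masks = generate_synthetic_run(spec, _DESIGN)
    roi_ts = data[masks["motor"]].mean(axis=0)
    expected = 1000.0 * (1.0 + 0.03 * boxcar)
    assert np.array_equal(roi_ts, expected)
    # voxels outside every ROI stay at baseline
    outside = ~(masks["motor"] | masks["caudate"])
    assert np.ptp(data[outside]) == 0


def test_fixed_seed_reproduces_run_bit_exactly():
    a, _, _ = generate_synthetic_run(_small_spec(1.0, 3.0), _DESIGN)
    b, _, _ = generate_synthetic_run(_small_spec(1.0, 3.0), _DESIGN)
    assert np.array_equal(a, b)


def test_different_seed_changes_noise():
    a, _, _ = generate_synthetic_run(_small_spec(1.0, 3.0, seed=3), _DESIGN)
    b, _, _ = generate_synthetic_run(_small_spec(1.0, 3.0, seed=4), _DESIGN)
    assert not np.array_equal(a, b)


# ---------------------------------------------------------------------------
# scanner simulator
# ---------------------------------------------------------------------------

def test_scanner_sim_conserves_file_count_and_renames_series(tmp_path):
    spec = _small_spec(1.0, 3.0, nt=4)
    data, _, _ = generate_synthetic_run(spec, _TINY_DESIGN)
    src = tmp_path / "scanner"
    paths = write_fixture_series(data, "mosaic", src, geometry=spec.geometry(),
                                 series="000013")
    emitted = run_scanner_sim(src, "000013", tr_ms=5, new_series="000014",
                              out_dir=tmp_path / "live")
    assert len(emitted) == len(paths) == 4
    assert all(p.name.startswith("000014_") for p in emitted)


@pytest.mark.parametrize("dialect", ["slice2d", "parrec"])
def test_scanner_sim_emission_cadence_does_not_change_results(tmp_path, dialect):
    """TR only paces emission: volumes assembled from the re-emitted series
    equal those from the source series."""
    spec = _small_spec(1.0, 3.0, nt=3)
    data, _, _ = generate_synthetic_run(spec, _TINY_DESIGN)
    src = tmp_path / "scanner"
    paths = write_fixture_series(data, dialect, src, geometry=spec.geometry(),
                                 series="000013")
    emitted = run_scanner_sim(src, "000013", tr_ms=1, new_series="000019",
                              out_dir=tmp_path / "live")
    src_vols = list(assemble_files(as_raw_files(paths, dialect), dialect))
    new_vols = list(assemble_files(as_raw_files(emitted, dialect), dialect))
    assert len(new_vols) == len(src_vols) == 3
    for a, b in zip(src_vols, new_vols):
        assert a.vol_idx == b.vol_idx
        assert np.array_equal(np.asarray(a.data), np.asarray(b.data))


def test_scanner_sim_unknown_series_errors(tmp_path):
    (tmp_path / "x.txt").write_text("not a scan")
    with pytest.raises(ConfigurationError):
        run_scanner_sim(tmp_path, "000013", tr_ms=1)


# ---------------------------------------------------------------------------
# stream simulator
# ---------------------------------------------------------------------------

def test_stream_sim_random_mode_defaults_give_60_timepoints(tmp_path):
    """Random mode at default dims (64, 64, 18, 60) produces a 60-volume run."""
    rois = default_rois((64, 64, 18))
    session = ScanSession(
        num_timepts=60, mask=Mask(data=rois["motor"]), analysis_choice="average",
        estimate_motion=False, output_dir=tmp_path,
    )
    engine = RealtimeEngine(session)
    thread, holder = run_engine_in_thread(engine, accept_timeout=30)
    sent = run_stream_sim(source=None, tr_ms=2, port=holder["scanner_port"], seed=1)
    thread.join(timeout=60)
    assert sent == 60
    assert engine.timeseries.n_filled == 60
    assert len(engine.store) == 60


def test_stream_sim_from_nifti_file(tmp_path):
    import nibabel as nib

    spec = _small_spec(1.0, 3.0, nt=6)
    data, _, _ = generate_synthetic_run(spec, _TINY_DESIGN)
    nifti = tmp_path / "func.nii.gz"
    nib.save(nib.Nifti1Image(data, spec.geometry().affine_ras), str(nifti))
    rois = default_rois((16, 16, 6))
    session = ScanSession(
        num_timepts=6, mask=Mask(data=rois["motor"]), analysis_choice="average",
        estimate_motion=False, output_dir=tmp_path,
    )
    engine = RealtimeEngine(session)
    thread, holder = run_engine_in_thread(engine, accept_timeout=30)
    sent = run_stream_sim(source=nifti, tr_ms=2, port=holder["scanner_port"])
    thread.join(timeout=30)
    assert sent == 6
    assert np.array_equal(engine.timeseries.buffer, data)
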