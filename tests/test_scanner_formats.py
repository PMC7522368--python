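"""Vendor dialect reading, volume assembly, and RAS+ reorientation."""

import itertools
import threading
import time

import numpy as np
import pytest
from nibabel import orientations as nbo

from rtfmri.errors import FormatError
from rtfmri.geometry import compute_ras_affine
from rtfmri.scanner_formats import (
    assemble_files,
    demosaic,
    mosaicify,
    read_parrec,
    stack_slices,
    watch_directory,
)
from rtfmri.simulator import (
    BlockDesign,
    SyntheticSpec,
    generate_synthetic_run,
    write_fixture_series,
    write_parrec_pair,
)

from conftest import as_raw_files


def _tiny_run(num_timepts, seed):
    """Noise-only synthetic run long enough for a 1 s / 1-block design."""
    spec = SyntheticSpec(
        dims=(16, 16, 6), num_timepts=num_timepts, seed=seed, signal_rois={}
    )
    design = BlockDesign(block_seconds=1.0, n_task_blocks=1, tr_ms=1000.0)
    data, _, _ = generate_synthetic_run(spec, design)
    return spec, data


# ---------------------------------------------------------------------------
# directory watching
# ---------------------------------------------------------------------------

def test_watch_empty_directory_yields_nothing(tmp_path):
    assert list(watch_directory(tmp_path, poll_interval=0.01, timeout=0.1)) == []


def test_watch_ignores_preexisting_files(tmp_path):
    (tmp_path / "old.dcm").write_bytes(b"x")
    assert list(watch_directory(tmp_path, poll_interval=0.01, timeout=0.1)) == []


def test_watch_emits_each_new_file_once_in_write_order(tmp_path):
    written = []

    def writer():
        for i in range(3):
            time.sleep(0.05)
            p = tmp_path / f"{i:03d}.dcm"
            p.write_bytes(b"x")
            written.append(p.name)

    t = threading.Thread(target=writer)
    t.start()
    events = [
        f.path.name
        for f in watch_directory(
            tmp_path, poll_interval=0.01, timeout=2.0, expected_count=3
        )
    ]
    t.join()
    assert events == written
    assert len(set(events)) == 3


# ---------------------------------------------------------------------------
# mosaics
# ---------------------------------------------------------------------------

def test_demosaic_identity_single_tile(rng):
    tile = rng.integers(0, 100, size=(8, 8)).astype(np.int16)
    out = demosaic(tile, 8, 8, 1)
    assert out.shape == (8, 8, 1)
    assert np.array_equal(out[:, :, 0], tile)


def test_demosaic_2x2_constant_tiles():
    # brute-force oracle: tile (r, c) holds constant value, becomes slice r*2+c
    mosaic = np.block([[np.full((4, 4), 10), np.full((4, 4), 20)],
                       [np.full((4, 4), 30), np.full((4, 4), 40)]])
    out = demosaic(mosaic, 4, 4, 4)
    assert [int(out[:, :, s].mean()) for s in range(4)] == [10, 20, 30, 40]
    assert all(np.ptp(out[:, :, s]) == 0 for s in range(4))


@pytest.mark.parametrize("n_slices", [1, 2, 4, 5, 9, 18])
def test_mosaic_roundtrip_random(rng, n_slices):
    vol = rng.integers(0, 4096, size=(16, 16, n_slices)).astype(np.int16)
    out = demosaic(mosaicify(vol), 16, 16, n_slices)
    assert np.array_equal(out, vol)


def test_demosaic_rejects_non_divisible_dims():
    with pytest.raises(FormatError):
        demosaic(np.zeros((10, 10)), 3, 3, 4)


def test_demosaic_rejects_excess_slices():
    with pytest.raises(FormatError):
        demosaic(np.zeros((8, 8)), 4, 4, 5)


# ---------------------------------------------------------------------------
# slice stacking
# ---------------------------------------------------------------------------

def test_stack_single_slice():
    sl = np.arange(12).reshape(3, 4)
    out = stack_slices([(sl, 0.0)])
    assert out.shape == (3, 4, 1)
    assert np.array_equal(out[:, :, 0], sl)


def test_stack_is_invariant_to_arrival_order(rng):
    slices = [(rng.integers(0, 100, size=(6, 6)), float(z)) for z in range(5)]
    sorted_out = stack_slices(list(slices))
    for perm in itertools.islice(itertools.permutations(slices), 0, 120, 17):
        assert np.array_equal(stack_slices(list(perm)), sorted_out)


def test_stack_rejects_duplicate_positions():
    with pytest.raises(FormatError):
        stack_slices([(np.zeros((2, 2)), 1.0), (np.zeros((2, 2)), 1.0)])


# ---------------------------------------------------------------------------
# PAR/REC
# ---------------------------------------------------------------------------

def test_parrec_roundtrip_bit_identical(tmp_path, rng, small_geometry):
    data = rng.integers(0, 4096, size=(16, 16, 6, 3)).astype(np.int16)
    par, _rec = write_parrec_pair(data, tmp_path / "fix_0001", small_geometry)
    read, geom = read_parrec(par)
    assert np.array_equal(read.astype(np.int16), data)
    assert read.shape[3] == 3
    assert geom.voxel_size_mm == (3.0, 3.0, 4.0)


def test_parrec_single_timepoint_keeps_4d(tmp_path, rng, small_geometry):
    data = rng.integers(0, 100, size=(16, 16, 6, 1)).astype(np.int16)
    par, _ = write_parrec_pair(data, tmp_path / "one_0001", small_geometry)
    read, _ = read_parrec(par)
    assert read.ndim == 4 and read.shape[3] == 1


def test_parrec_truncated_rec_errors(tmp_path, rng, small_geometry):
    data = rng.integers(0, 100, size=(16, 16, 6, 2)).astype(np.int16)
    par, rec = write_parrec_pair(data, tmp_path / "bad_0001", small_geometry)
    rec.write_bytes(rec.read_bytes()[: rec.stat().st_size // 2])
    with pytest.raises(FormatError):
        read_parrec(par)


# ---------------------------------------------------------------------------
# RAS+ reorientation
# ---------------------------------------------------------------------------

def test_ras_affine_identity_for_ras_input():
    aff = np.diag([2.0, 2.0, 3.0, 1.0])
    op, out_aff = compute_ras_affine(aff, (4, 4, 4))
    assert op.is_identity
    assert np.allclose(out_aff, aff)


def test_ras_affine_lr_flip_preserves_corner_coordinates(rng):
    # pure L/R flip: x axis points leftward
    aff = np.diag([-2.0, 2.0, 3.0, 1.0])
    aff[:3, 3] = [6.0, 0.0, 0.0]
    shape = (4, 3, 2)
    data = rng.normal(size=shape)
    op, out_aff = compute_ras_affine(aff, shape)
    out = op.apply(data)
    # oracle: world coordinate of every corner voxel is preserved
    inv = np.linalg.inv(aff)
    for corner in itertools.product([0, shape[0] - 1], [0, shape[1] - 1], [0, shape[2] - 1]):
        world = out_aff @ np.array(list(corner) + [1.0])
        src = np.rint(inv @ world).astype(int)[:3]
        assert out[corner] == data[tuple(src)]
    assert np.all(np.sign(np.diag(out_aff)[:3]) == 1)


def _signed_permutation_affines():
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product([1, -1], repeat=3):
            m = np.zeros((4, 4))
            m[3, 3] = 1.0
            for out_ax, (in_ax, s) in enumerate(zip(perm, signs)):
                m[out_ax, in_ax] = s
            yield m


def test_ras_affine_brute_force_over_48_signed_permutations(rng):
    """Exhaustive oracle: for every signed axis permutation, the reoriented
    volume must match the one found by brute-force search over operators."""
    shape = (3, 4, 5)
    data = rng.normal(size=shape)
    for aff in _signed_permutation_affines():
        op, out_aff = compute_ras_affine(aff, shape)
        out = op.apply(data)
        # brute force: try all 48 (perm, flips) operators, keep the one whose
        # composed affine is closest to RAS+ diagonal-positive
        best = None
        for perm in itertools.permutations(range(3)):
            for flips in itertools.product([1, -1], repeat=3):
                cand = data.transpose(perm)[
                    :: flips[0], :: flips[1], :: flips[2]
                ]
                # voxel->world for candidate: check world coords of all voxels
                ok = True
                inv = np.linalg.inv(aff)
                for idx in np.ndindex(cand.shape):
                    world = out_aff @ np.array(list(idx) + [1.0])
                    src = np.rint(inv @ world).astype(int)[:3]
                    if cand[idx] != data[tuple(src)]:
                        ok = False
                        break
                if ok:
                    best = cand
                    break
            if best is not None:
                break
        assert best is not None
        assert np.array_equal(out, best)
        # dominant directions are +R +A +S
        assert np.all(np.argmax(np.abs(out_aff[:3, :3]), axis=0) == [0, 1, 2])
        assert np.all(out_aff[:3, :3][np.arange(3), np.arange(3)] > 0)


def test_ras_affine_is_idempotent():
    for aff in itertools.islice(_signed_permutation_affines(), 0, 48, 7):
        _op, out_aff = compute_ras_affine(aff, (3, 4, 5))
        op2, _ = compute_ras_affine(out_aff, (3, 4, 5))
        assert op2.is_identity


# ---------------------------------------------------------------------------
# full assembly from fixture series
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dialect", ["slice2d", "mosaic", "parrec"])
def test_assembled_volumes_equal_reoriented_source(tmp_path, rng, dialect):
    spec, data = _tiny_run(num_timepts=4, seed=7)
    geom = spec.geometry()
    paths = write_fixture_series(data, dialect, tmp_path, geometry=geom)
    files = as_raw_files(paths, dialect)
    vols = list(assemble_files(files, dialect))
    assert [v.vol_idx for v in vols] == list(range(4))
    if dialect == "parrec":
        _d, g = read_parrec(paths[0])
        native_aff = g.affine_ras
    else:
        native_aff = geom.affine_ras
    ornt = nbo.io_orientation(native_aff)
    for t, v in enumerate(vols):
        expected = nbo.apply_orientation(data[..., t], ornt)
        assert np.array_equal(np.asarray(v.data, dtype=np.int16), expected)


@pytest.mark.parametrize("dialect", ["slice2d", "mosaic"])
def test_assembly_emits_in_order_despite_shuffled_arrival(tmp_path, rng, dialect):
    spec, data = _tiny_run(num_timepts=5, seed=9)
    paths = write_fixture_series(data, dialect, tmp_path, geometry=spec.geometry())
    shuffled = list(paths)
    rng.shuffle(shuffled)
    vols = list(assemble_files(as_raw_files(shuffled, dialect), dialect))
    assert [v.vol_idx for v in vols] == list(range(5))
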