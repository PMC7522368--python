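# Methods

## Architecture

The toolkit is split into two processes joined by TCP so each can run where
its data lives: the scanner side (directory watching, vendor-format
assembly, RAS+ reorientation, streaming) and the analysis side (4D buffer,
motion estimation, per-volume analysis, results serving). A volume crosses
the wire in two waves — a UTF-8 JSON header (timepoint index, shape,
element type, byte/axis order, voxel size) followed by the raw array buffer
— each as a 4-byte length-prefixed frame, acknowledged per volume. Payloads
are Fortran-ordered (x fastest) and the header records this, so the stream
is self-describing; the codec round-trip is bit-exact for all eight
supported integer/float element types. Remote clients request results over
a separate request/reply channel: the request is the 0-based volume index
as 4-digit zero-padded text (runs < 10000 timepoints), the reply JSON with
`foundResults` false/true plus the stored name/value pairs, nulls
preserved. Requests never block on processing.

## Vendor dialects and orientation

Per-slice DICOM (GE-style) files are grouped into volumes in contiguous
blocks of `n_slices` by instance number — scanners differ in how they
interleave instance numbers across volumes, and the contiguous-block
convention is the one the fixture writer also uses — and stacked ascending
by position along the slice normal. Mosaic DICOM (Siemens-style) files are
de-tiled from a row-major square grid of `ceil(sqrt(n_slices))²` tiles (the
standard mosaic convention), with the slice count carried in a private tag.
PAR/REC pairs are read through nibabel; the fixture writer emits a
V4.2-style text header with rescale slope/intercept 1/0 so voxel values
pass through unchanged. Readers tolerate files carrying only the tags
actually used (dims, pixel spacing, orientation/position, series/instance
numbers, pixel data) and retry three times on parse failure so partially
written files are simply read on a later poll.

Directory watching is poll-based (default 50 ms) rather than
OS-event-based: portable and deterministic under test; files present before
watching begins are never emitted, and new files within one poll cycle are
emitted in lexicographic order, which matches vendors' zero-padded
numbering. Volumes are released strictly in increasing timepoint order with
no gaps, buffering any volume that completes early.

The voxel-to-world affine is built from the DICOM orientation/position tags
(or the PAR header) and every volume is reoriented to RAS+ axis order via
the nearest signed axis permutation before leaving the scanner side; the
composed affine preserves each voxel's world coordinate exactly, and
reorientation is idempotent. Element type is preserved from file to buffer;
conversion to float64 happens only at analysis.

## Motion estimation

Per volume, a 6-parameter rigid transform (3 translations in mm, 3
rotations about the volume center) is estimated against (a) the first
received volume and (b) the previous volume, by maximizing mutual
information of the 32×32 joint intensity histogram over jointly min-max
scaled intensities. Optimization is coordinate descent with per-parameter
step halving at two resolution levels (in-plane 2× downsampled, then full
resolution; translation steps from 2 voxels down to 0.05 of a voxel,
rotations from 0.05 rad down to 0.002). The reported scalar is the mean
Euclidean displacement (mm) under the estimated transform of voxels inside
an intensity-derived brain support (reference voxels above 10% of the 98th
percentile). On smooth phantoms, pure translations up to 2 voxels are
recovered well within 0.25 voxel-equivalent mm (typically < 0.1 mm);
identical volumes short-circuit to exactly zero, and flat (zero-variance)
volumes report zero with a warning rather than failing mid-scan.

Analyses always receive the raw volume; motion is estimated and recorded
alongside, never applied. There is no online denoising or detrending —
users needing either can implement it inside a custom analysis script.

## Analyses and the plugin contract

Built-in statistics are the (optionally mask-weighted) mean and the median
over in-mask voxels; both match brute-force voxel loops to 1e-10 relative.
A custom analysis is any script defining `CustomAnalysis` with an
initializer (given the session mask, timepoint count, and TR; state
persists across calls) and `compute(vol, vol_idx) -> dict`. Missing entry
points fail at setup, before the scan; exceptions inside `compute` during
the scan are logged and recorded as an empty result — in a real-time
session, robustness beats strictness. The shipped rolling-correlation
plugin stores each ROI's mean signal at the current timepoint and, once
`vol_idx > corr_window` (window 10), returns the Pearson r over indices
`[vol_idx − corr_window, vol_idx)`. That slice deliberately excludes the
current timepoint, reproducing the reference neurofeedback recipe exactly
(hence 11 leading nulls); `include_current=True` gives the window ending at
the current volume. Constant windows return null with a warning. Whether r
should be Fisher-z transformed before being used as feedback is left to
the user's script; the plugin reports plain r.

## Synthetic data

The generator emulates a block-design hand-squeeze run: alternating
equal-length task/rest blocks (defaults 20 s, five task blocks, TR 1000 ms;
any remainder is leading rest, so a 208-timepoint run is 8 rest volumes
plus five 20+20 cycles). In-ROI voxels follow
`baseline × (1 + amplitude · boxcar(t))` plus Gaussian noise of SD
`noise_sd%` of baseline; defaults are a 1000-unit baseline, 3% amplitude,
and 1% noise — a deliberately clean, robust motor response. Two built-in
ellipsoid ROIs (a larger "motor", a smaller deeper "caudate") fit any
requested dims, default 64×64×18 with 3×3×4 mm voxels. Output is int16 by
default, as scanner files carry integer intensities; a fixed seed
reproduces the run bit-exactly.

What the generator does *not* emulate — hemodynamic lag and dispersion,
slow drifts, physiological noise, spatial autocorrelation, actual subject
motion — bounds what passing tests show: they validate the plumbing
(assembly, transport, bookkeeping, statistics) and signal recovery under
idealized noise, not detection power on real data.

## Problem sizes and pacing

Tests and the acceptance script run full sessions at the reference session
geometry (64×64×18 volumes, 60- and 208-timepoint runs) but pace the
simulators at a few ms per volume rather than the 1000 ms default; pacing
only schedules file/volume emission and cannot affect results (asserted by
a cadence-invariance test). Motion estimation is exercised on dedicated
phantom runs and on short streamed sessions; the large streamed sessions
disable it so a full simulated session completes in seconds.

## Numerical and design choices

- Timepoint indices are 0-based everywhere; fixture file naming uses the
  vendors' 1-based numbering.
- Duplicate timepoints: first write wins, with a logged error; out-of-range
  indices are protocol errors.
- Median of an even in-mask count is the mean of the central pair.
- Mask binarization keeps voxels with value ≥ threshold on the native
  intensity scale (a 0–100 probabilistic atlas cut at "10%" is cut at 10);
  an all-zero result is an error, not an empty mask.
- The whole-brain mask keeps voxels above 10% of the robust (98th
  percentile) maximum, selects the largest connected component, and fills
  holes. MNI-to-functional mask registration is delegated to external
  registration tooling and is out of scope here.
- Run outputs land in auto-incrementing `pyneal_NNN` directories (next =
  highest existing + 1, collision-safe); `results.json` is keyed by
  stringified volume index with nulls preserved, and `receivedFunc.nii.gz`
  reproduces the received buffer bit-exactly.
- Config files are YAML; parsed values are persisted back so the next
  launch starts from the last-used settings. The scanner-side file uses
  exactly the keys `pynealSocketHost`, `pynealSocketPort`,
  `scannerBaseDir`, `scannerMake`.
- All TCP messaging is stdlib sockets with explicit length-prefixed
  framing; default endpoints are 127.0.0.1 with scanner port 5555 and
  results port 5558.

## Known limitations

Multiband acquisitions are not supported; DICOM handling is deliberately
minimal rather than conformance-complete; there is no online denoising,
GLM, or classification built-in; the results server serves request/reply
only (no push); and motion is estimated, never corrected.
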