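# rtfmri

Real-time fMRI streaming and analysis: a scanner-side process that converts
vendor image files into standardized RAS+ volumes and streams them one
timepoint at a time, plus an analysis-side engine that buffers each volume,
estimates head motion, computes ROI statistics (built-in or user-written),
and serves per-volume results to remote clients mid-scan. Simulators and a
synthetic block-design generator let the entire loop run with no scanner.

## Who this is for

Neuroimaging researchers running real-time fMRI experiments —
neurofeedback, online quality monitoring, or brain-state-dependent
experimental control — who need the volume-by-volume signal from a region
of interest available to stimulus software *during* the scan, not after it.

## What it computes

A scan is an ordered series of 3D volumes `v_t`, one per repetition time
(TR). For each incoming volume the engine computes, within an ROI mask `w`:

- **unweighted mean**: mean of `v_t[i]` over voxels with `w[i] > 0`
- **weighted mean**: `Σᵢ wᵢ v_t[i] / Σᵢ wᵢ`
- **median** over in-mask voxels, or
- any **custom analysis**: a user script whose `CustomAnalysis.compute(vol,
  vol_idx)` returns a dict of named values. The shipped reference plugin
  computes the rolling Pearson correlation between two ROI mean signals
  over the preceding `corr_window = 10` timepoints (null until the window
  fills).

Alongside, rigid-body head motion is estimated per volume by
mutual-information histogram registration against a fixed reference volume
(absolute motion) and the previous volume (relative motion), reported as
mean displacement in mm of in-brain voxels.

Three scanner file dialects are supported on the acquisition side:
per-slice 2D DICOM (GE-style), per-volume mosaic DICOM (Siemens-style), and
PAR/REC pairs (Philips-style). Every assembled volume is reoriented to RAS+
before analysis, so masks and analyses are orientation-agnostic.

## Worked example

`examples/stream_and_analyze.py` generates a 64×64×18×60 synthetic run with
a 3% task signal in a motor ROI (five alternating 5 s task / 5 s rest
blocks), streams it to the engine over TCP, and reads the written results
document:

```
streamed 60 volumes; run output in scratch/example_output/pyneal_001
vol   0 (rest): motor ROI average = 999.78
vol  12 (task): motor ROI average = 1029.80
vol  30 (task): motor ROI average = 1030.14
vol  59 (rest): motor ROI average = 999.45
task volumes sit ~3% above the 1000-unit rest baseline
```

The per-volume ROI average tracks the 1000-unit baseline during rest and
rises by ~30 units (3%) during task blocks — the signal a neurofeedback
display would present. Each run directory (`pyneal_001`, `pyneal_002`, …)
contains `receivedFunc.nii.gz` (the 4D data exactly as received),
`results.json` (one entry per timepoint), `motion.tsv`, `timing.tsv`, and a
log.

Other examples: `full_scanner_loop.py` (file watching + assembly +
streaming end to end), `rolling_correlation.py` (two-ROI connectivity
feedback), `results_client.py` (a remote End-User request),
`generate_synthetic_run.py`, `prepare_mask.py`.

Command-line entry points mirror the library: `rtscanner --config
scannerConfig.yaml` (scanner side), `rtengine --config session.yaml`
(analysis side), and `rtsim scanner|stream` (simulators).

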