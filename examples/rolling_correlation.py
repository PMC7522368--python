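"""Two-ROI connectivity neurofeedback with the rolling-correlation plugin.

Feeds a 60-timepoint synthetic run through the engine with the shipped
RollingCorrelation analysis: the per-volume result is the Pearson r between
the motor and caudate ROI mean signals over the previous 10 timepoints.
The first 11 volumes return null (the window has not filled); afterwards r
is high because both ROIs carry the same task signal.
"""

from rtfmri.analysis_plugins import RollingCorrelation
from rtfmri.realtime_engine import RealtimeEngine, ScanSession
from rtfmri.scanner_formats import AssembledVolume
from rtfmri.session_io import Mask
from rtfmri.simulator import BlockDesign, SyntheticSpec, default_rois, generate_synthetic_run

rois = default_rois((64, 64, 18))
spec = SyntheticSpec(
    dims=(64, 64, 18), num_timepts=60, seed=8,
    signal_rois={k: (v, 3.0) for k, v in rois.items()},
)
data, _, _ = generate_synthetic_run(spec, BlockDesign(block_seconds=5.0, n_task_blocks=5))

plugin = RollingCorrelation((rois["motor"], rois["caudate"]), num_timepts=60)
session = ScanSession(
    num_timepts=60, mask=Mask(data=rois["motor"]), analysis_choice="custom",
    custom_analysis=plugin, estimate_motion=False, output_dir="scratch/example_corr",
)
engine = RealtimeEngine(session)
geom = spec.geometry()
for t in range(60):
    engine.process_volume(AssembledVolume(vol_idx=t, data=data[..., t], geometry=geom))

results = engine.store.as_dict()
nulls = sum(1 for v in results.values() if v["corr"] is None)
print(f"warm-up volumes with null r: {nulls} (window 10 + current-volume guard)")
for t_idx in (5, 11, 30, 59):
    r = results[t_idx]["corr"]
    print(f"vol {t_idx:3d}: r = {'null' if r is None else f'{r:+.3f}'}")
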