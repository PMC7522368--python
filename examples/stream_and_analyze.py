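"""Stream a synthetic run to the engine over TCP and read back the results.

Runs the analysis engine (listening on an ephemeral port) in a background
thread, streams a 60-timepoint synthetic dataset one volume at a time, and
prints a few per-volume ROI averages from the written results document.
The pacing is set to 5 ms/volume so the demo finishes in about a second;
results are identical at any pacing.
"""

import threading

from rtfmri.realtime_engine import RealtimeEngine, ScanSession
from rtfmri.session_io import Mask, read_results_json
from rtfmri.simulator import (
    BlockDesign, SyntheticSpec, default_rois, generate_synthetic_run, run_stream_sim,
)

rois = default_rois((64, 64, 18))
spec = SyntheticSpec(
    dims=(64, 64, 18), num_timepts=60, seed=3,
    signal_rois={k: (v, 3.0) for k, v in rois.items()},
)
data, boxcar, _ = generate_synthetic_run(spec, BlockDesign(block_seconds=5.0, n_task_blocks=5))

session = ScanSession(
    num_timepts=60, mask=Mask(data=rois["motor"]), analysis_choice="average",
    estimate_motion=False, output_dir="scratch/example_output",
)
engine = RealtimeEngine(session)
holder = {}

def run_engine():
    holder["run_dir"] = engine.run(scanner_port=0, results_port=0)

t = threading.Thread(target=run_engine, daemon=True)
t.start()
while not hasattr(engine, "bound_scanner_port"):
    pass
sent = run_stream_sim(source=data, tr_ms=5, port=engine.bound_scanner_port)
t.join()

results = read_results_json(holder["run_dir"] / "results.json")
print(f"streamed {sent} volumes; run output in {holder['run_dir']}")
for t_idx in (0, 12, 30, 59):
    state = "task" if boxcar[t_idx] else "rest"
    print(f"vol {t_idx:3d} ({state}): motor ROI average = {results[t_idx]['average']:.2f}")
print("task volumes sit ~3% above the 1000-unit rest baseline")
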