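"""The complete scanner-to-results loop with no scanner.

1. writes a synthetic run as a Siemens-style mosaic DICOM series,
2. starts the analysis engine (ingest + ROI average + results server),
3. starts the scanner-side pipeline watching a session directory,
4. replays the series into that directory one volume per pacing interval,
   exactly as a scanner would.

Prints the volume counts at each stage; all three should equal 60.
"""

import tempfile
import threading
from pathlib import Path

from rtfmri.pipeline import run_scanner_pipeline
from rtfmri.realtime_engine import RealtimeEngine, ScanSession
from rtfmri.session_io import Mask, read_results_json
from rtfmri.simulator import (
    BlockDesign, SyntheticSpec, default_rois, generate_synthetic_run,
    run_scanner_sim, write_fixture_series,
)

rois = default_rois((64, 64, 18))
spec = SyntheticSpec(
    dims=(64, 64, 18), num_timepts=60, seed=21,
    signal_rois={k: (v, 3.0) for k, v in rois.items()},
)
data, _, _ = generate_synthetic_run(spec, BlockDesign(block_seconds=5.0, n_task_blocks=5))

with tempfile.TemporaryDirectory() as td:
    td = Path(td)
    source = td / "source"
    write_fixture_series(data, "mosaic", source, geometry=spec.geometry(), series="000013")
    live = td / "data"
    live.mkdir()

    session = ScanSession(
        num_timepts=60, mask=Mask(data=rois["motor"]), analysis_choice="average",
        estimate_motion=False, output_dir=td / "output",
    )
    engine = RealtimeEngine(session)
    holder = {}

    def run_engine():
        holder["run_dir"] = engine.run(scanner_port=0, results_port=0)

    et = threading.Thread(target=run_engine, daemon=True)
    et.start()
    while not hasattr(engine, "bound_results_port"):
        pass

    ready = threading.Event()
    sent = {}

    def pipeline():
        sent["n"] = run_scanner_pipeline(
            live, "mosaic", host="127.0.0.1", port=engine.bound_scanner_port,
            poll_interval=0.01, timeout=60, ready_event=ready,
        )

    pt = threading.Thread(target=pipeline, daemon=True)
    pt.start()
    ready.wait()

    emitted = run_scanner_sim(source, "000013", tr_ms=20, new_series="000014", out_dir=live)
    pt.join()
    et.join()

    results = read_results_json(holder["run_dir"] / "results.json")
    print(f"mosaic files emitted by the scanner simulator: {len(emitted)}")
    print(f"volumes assembled and streamed by the pipeline: {sent['n']}")
    print(f"result entries recorded by the engine:          {len(results)}")
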