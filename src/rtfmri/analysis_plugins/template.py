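"""Template for user-written custom analysis scripts.

Copy this file, rename it, and point the session config's
``customAnalysisFile`` at it. The engine instantiates ``CustomAnalysis``
once before the scan and calls ``compute`` on every incoming volume; any
state assigned in ``__init__`` persists across calls. ``compute`` must
return a dict of named, JSON-serializable results (numbers or None); the
engine merges it into that volume's result entry, which remote clients can
request mid-scan by volume index.
"""

import numpy as np


class CustomAnalysis:
    def __init__(self, mask, num_timepts, tr_ms, **kwargs):
        """Runs once, before the scan.

        Parameters
        ----------
        mask : rtfmri.session_io.Mask
            The mask selected in the session config. Use it or ignore it
            and load your own ROIs here.
        num_timepts : int
            Total volumes expected this run; useful for preallocation.
        tr_ms : float
            Repetition time in milliseconds.
        """
        self.mask = mask.data > 0
        self.num_timepts = num_timepts
        self.tr_ms = tr_ms

    def compute(self, vol, vol_idx):
        """Runs on every incoming volume.

        Parameters
        ----------
        vol : 3D ndarray
            The raw volume for this timepoint (RAS+ axis order).
        vol_idx : int
            0-based timepoint index; increases monotonically across calls.
        """
        return {"average": float(np.mean(vol[self.mask]))}
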