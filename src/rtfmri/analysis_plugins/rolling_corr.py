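"""Sliding-window correlation between two ROIs.

On each volume the mean signal inside each ROI is stored at that volume's
timepoint. Once more than ``corr_window`` timepoints have accumulated
(``vol_idx > corr_window``), the Pearson r between the two ROI series over
the window ``[vol_idx - corr_window, vol_idx)`` is returned; before that the
result is null. Note the window deliberately excludes the current
timepoint - this reproduces the reference neurofeedback recipe verbatim;
set ``include_current=True`` for a window ending at the current volume.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from ..session_io import Mask

log = logging.getLogger(__name__)

DEFAULT_CORR_WINDOW = 10


class RollingCorrelation:
    """Two-ROI rolling Pearson correlation, one r-value per volume.

    Parameters
    ----------
    masks : pair of 3D arrays or Mask
        The two ROIs; any positive voxel belongs to the ROI.
    num_timepts : int
        Run length; per-ROI signal arrays are preallocated to this length.
    corr_window : int
        Number of preceding timepoints the correlation is computed over.
    include_current : bool
        If True, the window is ``(vol_idx - corr_window, vol_idx]`` instead
        of the default current-volume-excluding slice.
    """

    def __init__(self, masks, num_timepts: int,
                 corr_window: int = DEFAULT_CORR_WINDOW,
                 include_current: bool = False, **_ignored) -> None:
        if corr_window < 2:
            raise ValueError("corr_window must be >= 2")
        if corr_window >= num_timepts:
            raise ValueError("corr_window must be smaller than num_timepts")
        m1, m2 = masks
        self.masks = (
            np.asarray(m1.data if isinstance(m1, Mask) else m1) > 0,
            np.asarray(m2.data if isinstance(m2, Mask) else m2) > 0,
        )
        self.vals = (np.zeros(num_timepts), np.zeros(num_timepts))
        self.num_timepts = num_timepts
        self.corr_window = corr_window
        self.include_current = include_current

    def compute(self, vol: np.ndarray, vol_idx: int) -> dict:
        for roi_vals, roi_mask in zip(self.vals, self.masks):
            roi_vals[vol_idx] = np.mean(vol[roi_mask])
        if vol_idx > self.corr_window:
            shift = 1 if self.include_current else 0
            sl = slice(vol_idx - self.corr_window + shift, vol_idx + shift)
            ts1 = self.vals[0][sl]
            ts2 = self.vals[1][sl]
            if np.ptp(ts1) == 0 or np.ptp(ts2) == 0:
                log.warning(
                    "constant ROI signal in window ending at vol %d; r undefined",
                    vol_idx,
                )
                corr = None
            else:
                corr = float(stats.pearsonr(ts1, ts2)[0])
        else:
            corr = None
        return {"corr": corr}
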