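"""Prepare ROI masks: threshold/binarize an atlas and build a brain mask.

Mimics the usual mask workflow: a probabilistic atlas ROI (values 0-100) is
thresholded at 10 and binarized; a whole-brain mask is derived from one
example functional volume by intensity thresholding at 10% of the robust
maximum, keeping the largest connected component.
"""

import numpy as np

from rtfmri.session_io import make_whole_brain_mask, threshold_binarize

rng = np.random.default_rng(0)

# synthetic probabilistic atlas ROI: probabilities fall off from a center
x, y, z = np.meshgrid(np.arange(32), np.arange(32), np.arange(16), indexing="ij")
dist = np.sqrt((x - 10.0) ** 2 + (y - 16.0) ** 2 + (z - 8.0) ** 2)
atlas = np.clip(100 - 8 * dist, 0, 100)
roi = threshold_binarize(atlas, 10.0)
print(f"atlas voxels >= 10% probability kept: {int(roi.data.sum())}")

# example functional volume: bright head against dark background + noise
head = (dist < 14) * 1000.0 + rng.normal(0, 20, size=dist.shape)
brain = make_whole_brain_mask(head)
print(f"whole-brain mask voxels: {int(brain.data.sum())} "
      f"of {head.size} (head occupies {(dist < 14).sum()})")
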