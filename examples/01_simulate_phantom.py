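"""Render a synthetic CBCT-like phantom of an implanted electrode array.

Builds the deep-insertion 'confusion' preset for a widely spaced 12-contact
array, prints its geometry, and writes the volume plus ground truth to disk.
"""

import numpy as np

from cilocate import make_phantom, write_phantom

ph = make_phantom("confusion", "Flex 28", seed=0)
gt = ph.gt

chords = np.linalg.norm(np.diff(gt.positions, axis=0), axis=1)
print(f"array: {ph.spec.name} ({ph.spec.n_electrodes} contacts, spacing "
      f"{ph.spec.gap_distances[0]:.1f} mm)")
print(f"insertion angle at the apical contact: {gt.insertion_angle:.0f} deg")
print(f"inter-contact chord distances: {chords.min():.2f}-{chords.max():.2f} mm")
print(f"volume: {ph.volume.shape} voxels at {ph.volume.spacing[0]:.1f} mm")

write_phantom(ph, "scratch/phantom_confusion")
print("wrote volume (NIfTI) + ground-truth CSV/JSON to scratch/phantom_confusion/")

# The insertion angle is past one full turn and the chords match the array
# spacing, so contacts on adjacent spiral turns lie about one inter-electrode
# distance apart - the geometric precondition for apical-basal confusion.
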