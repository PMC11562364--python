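"""End-to-end localization: volume -> ROI -> candidates -> path -> refinement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import registry
from .candidates import CandidateSet, candidates_from_roi
from .pathfind import CostParams, ElectrodePath, find_path
from .refine import RefineParams, refine_path
from .registry import EASpec
from .volume import Volume, extract_roi

__all__ = ["LocalizationResult", "localize", "resolve_threshold"]


@dataclass
class LocalizationResult:
    """Everything produced along the localization chain for one volume."""

    path: ElectrodePath  # voxel-level chain
    refined: ElectrodePath | None  # sub-voxel chain (None when skipped)
    candidates: CandidateSet
    roi: Volume
    alpha1: float

    @property
    def positions(self) -> np.ndarray:
        """Final electrode positions (refined when available), base to apex."""
        return (self.refined or self.path).nodes


def resolve_threshold(mode, spec_name: str) -> float:
    """Threshold percent from a mode: a number, ``individual`` or ``generalized``."""
    if isinstance(mode, (int, float)):
        return float(mode)
    return registry.get_threshold(spec_name, mode)


def localize(
    volume: Volume,
    gt_positions: np.ndarray,
    spec: EASpec,
    alpha1: float,
    params: CostParams = CostParams(),
    refine_params: RefineParams | None = RefineParams(),
    roi_margin_mm: float = 3.0,
) -> LocalizationResult:
    """Run the full localization chain on one volume.

    The ROI is cropped around the reference coordinates with the given
    margin; the most basal reference coordinate seeds the path search (the
    published procedure's one piece of prior knowledge besides the array
    geometry).  Sub-voxel refinement runs only on complete paths; pass
    ``refine_params=None`` to skip it.
    """
    gt_positions = np.atleast_2d(np.asarray(gt_positions, dtype=float))
    roi = extract_roi(volume, gt_positions, roi_margin_mm)
    cands = candidates_from_roi(roi, alpha1)
    i_max = float(roi.intensities.max())
    path = find_path(cands, gt_positions[0], spec, params, i_max=i_max)
    refined = None
    if refine_params is not None and path.complete and len(path) >= 1:
        refined = refine_path(roi, path, spec, refine_params)
    return LocalizationResult(
        path=path, refined=refined, candidates=cands, roi=roi, alpha1=float(alpha1)
    )
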