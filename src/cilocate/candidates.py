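"""Candidate electrode locations from an ROI volume.

The pipeline is: cumulative-histogram threshold (retain the brightest
``alpha_1`` percent of ROI voxels) -> binary mask -> 3D topological thinning
(medial-axis skeletonization, connectivity- and endpoint-preserving).  Every
skeleton voxel becomes a candidate point carrying its world position and raw
voxel intensity.

Because the right ``alpha_1`` depends on the array (dim apical contacts need
a permissive threshold; a too-permissive one floods the mask with bone),
:func:`parametrize_threshold` sweeps a grid of thresholds and reports, for
each, the percentage of electrodes with at least one candidate within the
detection radius of ground truth — the curve from which per-array thresholds
are chosen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .volume import Volume

__all__ = [
    "CandidateSet",
    "cumulative_threshold",
    "binary_mask",
    "extract_candidates",
    "candidates_from_roi",
    "parametrize_threshold",
]


@dataclass
class CandidateSet:
    """Points eligible to be electrode locations.

    Attributes
    ----------
    points
        ``(n, 3)`` world coordinates in mm (skeleton voxel centres).
    intensities
        Raw voxel intensity at each point.
    alpha1
        Threshold (percent of ROI voxels retained) that produced the set.
    cutoff
        The resulting intensity cutoff.
    """

    points: np.ndarray
    intensities: np.ndarray
    alpha1: float | None = None
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.points)


def cumulative_threshold(roi: Volume, alpha1: float) -> float:
    """Intensity cutoff retaining the brightest ``alpha1`` percent of voxels.

    Returns the smallest intensity ``t`` such that the fraction of ROI voxels
    with intensity >= ``t`` is at most ``alpha1/100``; voxels tied with the
    cutoff are kept, so the retained count can exceed the nominal fraction by
    the tie multiplicity.  At least one voxel is always retained.
    """
    if not 0 < alpha1 < 100:
        raise ValueError(f"alpha1 must lie in (0, 100) percent, got {alpha1}")
    flat = roi.intensities.ravel()
    if flat.max() == flat.min():
        warnings.warn("constant ROI: threshold degenerates to the constant value")
        return float(flat[0])
    k = max(1, int(np.floor(alpha1 / 100.0 * flat.size)))
    # k-th largest intensity via partition
    cutoff = np.partition(flat, flat.size - k)[flat.size - k]
    return float(cutoff)


def binary_mask(roi: Volume, cutoff: float) -> np.ndarray:
    """Boolean grid, true where intensity >= cutoff."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return roi.intensities >= cutoff


def extract_candidates(mask: np.ndarray, roi: Volume) -> CandidateSet:
    """Skeletonize the mask; every centerline voxel becomes a candidate.

    Uses 3D medial-axis thinning (connectivity- and line-endpoint-preserving),
    so isolated blobs reduce to near-centre voxels and thin structures to
    their centerline.  An empty mask yields an empty candidate set.
    """
    if mask.shape != roi.shape:
        raise ValueError("mask and ROI shapes differ")
    if not mask.any():
        return CandidateSet(np.empty((0, 3)), np.empty(0))
    skel = skeletonize(mask)
    # Topological thinning may erode a small compact blob to nothing; every
    # connected component must survive (an isolated blob IS a potential
    # electrode), so such components contribute their brightest voxel.
    labels, n_comp = ndimage.label(skel | mask)
    kept = np.unique(labels[skel])
    for comp in range(1, n_comp + 1):
        if comp not in kept:
            comp_idx = np.argwhere(labels == comp)
            vals = roi.intensities[tuple(comp_idx.T)]
            peak = comp_idx[int(np.argmax(vals))]
            skel[tuple(peak)] = True
    idx = np.argwhere(skel)
    return CandidateSet(
        points=roi.index_to_world(idx),
        intensities=roi.intensities[skel],
    )


def candidates_from_roi(roi: Volume, alpha1: float) -> CandidateSet:
    """Threshold + mask + thinning in one call."""
    cutoff = cumulative_threshold(roi, alpha1)
    cs = extract_candidates(binary_mask(roi, cutoff), roi)
    cs.alpha1 = float(alpha1)
    cs.cutoff = float(cutoff)
    return cs


def coverage(cs: CandidateSet, gt_positions: np.ndarray, radius_mm: float = 0.9) -> float:
    """Percent of electrodes with >=1 candidate within ``radius_mm`` of GT."""
    gt_positions = np.atleast_2d(gt_positions)
    if len(cs) == 0:
        return 0.0
    tree = cKDTree(cs.points)
    d, _ = tree.query(gt_positions, k=1)
    return 100.0 * float(np.mean(d <= radius_mm))


def parametrize_threshold(
    roi: Volume,
    gt_positions: np.ndarray,
    lo: float = 0.01,
    hi: float = 3.0,
    step: float = 0.01,
    radius_mm: float = 0.9,
) -> tuple[pd.DataFrame, float]:
    """Sweep the candidate threshold and choose the per-array value.

    For each ``alpha_1`` on the grid ``lo, lo+step, ..., hi`` (defaults
    0.01–3.0 % in 0.01 % steps), computes the percentage of electrodes having
    at least one candidate point within ``radius_mm`` (default 0.9 mm) of the
    ground-truth position.  The chosen threshold is the smallest grid value
    attaining the maximum coverage — the most selective setting that still
    puts a candidate on every reachable electrode.

    Returns ``(curve, chosen_alpha1)`` where ``curve`` has columns
    ``alpha1_pct``, ``coverage_pct``, ``n_candidates``, ``cutoff``.
    """
    gt_positions = np.atleast_2d(np.asarray(gt_positions, dtype=float))
    if gt_positions.size == 0:
        raise ValueError("parametrize_threshold needs ground-truth positions")
    n_steps = int(round((hi - lo) / step))
    alphas = lo + step * np.arange(n_steps + 1)
    # Identical cutoffs give identical masks: group the grid by cutoff and
    # skeletonize once per distinct cutoff.
    rows = []
    prev_cutoff = None
    prev = None
    for a in alphas:
        cutoff = cumulative_threshold(roi, float(a))
        if cutoff != prev_cutoff:
            cs = extract_candidates(binary_mask(roi, cutoff), roi)
            prev = (len(cs), coverage(cs, gt_positions, radius_mm), cutoff)
            prev_cutoff = cutoff
        n_cand, cov, cutoff = prev
        rows.append((float(a), cov, n_cand, cutoff))
    curve = pd.DataFrame(
        rows, columns=["alpha1_pct", "coverage_pct", "n_candidates", "cutoff"]
    )
    best = curve["coverage_pct"].max()
    chosen = float(curve.loc[curve["coverage_pct"] == best, "alpha1_pct"].iloc[0])
    return curve, chosen
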