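"""Scoring of predicted electrode positions against ground truth.

Two headline metrics: the localization accuracy ``L_a`` (mean Euclidean
distance between same-labelled predicted and ground-truth electrodes, mm)
and the detection rate (percentage of electrodes whose prediction falls
within 0.9 mm — three voxels at the nominal 0.3 mm CBCT resolution — of
ground truth, inclusive).  When the predicted chain is shorter than the
array, the missing labels count as undetected and are excluded from the
``L_a`` mean but reported separately.

:func:`classify_errors` additionally labels the characteristic failure
modes of chain localization with automated, nearest-ground-truth sequence
heuristics: double detection (two chain nodes on the same electrode),
apical–basal confusion in either direction (the chain revisiting the basal
turn after ascending, or jumping apically early and descending), and
artifact detection (nodes far from every electrode).  These are reproducible
proxies for what is otherwise a manual visual classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalReport",
    "localization_accuracy",
    "detection_rate",
    "classify_errors",
    "evaluate",
    "DETECTION_RADIUS_MM",
]

DETECTION_RADIUS_MM = 0.9

ERROR_LABELS = (
    "artifact_detection",
    "double_detection",
    "ab_confusion_basal_revisit",
    "ab_confusion_reversal",
)


def _as_points(x) -> np.ndarray:
    return np.asarray(x, dtype=float).reshape(-1, 3)


def _paired_errors(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Per-label distances for labels present in both lists (pred may be short)."""
    if len(pred) > len(gt):
        raise ValueError(
            f"predicted chain has {len(pred)} labels but ground truth only {len(gt)}"
        )
    return np.linalg.norm(pred - gt[: len(pred)], axis=1)


def localization_accuracy(pred, gt) -> float:
    """Mean distance in mm between same-labelled predicted and GT electrodes.

    Labels are positional: entry ``k`` is electrode ``k+1`` from the base.
    A shorter prediction contributes only its present labels to the mean.
    """
    pred, gt = _as_points(pred), _as_points(gt)
    errs = _paired_errors(pred, gt)
    if errs.size == 0:
        raise ValueError("no paired labels to score")
    return float(errs.mean())


def detection_rate(pred, gt, radius_mm: float = DETECTION_RADIUS_MM) -> tuple[float, np.ndarray]:
    """Percent of electrodes detected, plus the per-electrode flag vector.

    Electrode ``k`` counts as detected iff its same-labelled prediction lies
    within ``radius_mm`` (inclusive).  Missing labels are undetected; the
    rate denominator is always the full electrode count.
    """
    pred, gt = _as_points(pred), _as_points(gt)
    errs = _paired_errors(pred, gt)
    flags = np.zeros(len(gt), dtype=bool)
    flags[: len(errs)] = errs <= radius_mm
    return 100.0 * float(flags.mean()), flags


def _nearest_gt_sequence(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(1-based nearest-GT index, distance to it) for each predicted node."""
    d = np.linalg.norm(pred[:, None, :] - gt[None, :, :], axis=2)
    return d.argmin(axis=1) + 1, d.min(axis=1)


def classify_errors(
    pred, gt, radius_mm: float = DETECTION_RADIUS_MM
) -> set[str]:
    """Automated labels for the characteristic localization failure modes.

    Each predicted node is assigned its nearest ground-truth electrode;
    the index sequence along the chain (base to apex) is then pattern-matched:

    ``double_detection``
        two or more nodes within ``radius_mm`` of the same electrode;
    ``ab_confusion_basal_revisit``
        the sequence climbs and then falls back by at least two indices —
        the chain re-descends onto the basal turn after ascending;
    ``ab_confusion_reversal``
        an early forward jump of more than one index followed by a
        monotonically descending tail — the chain crosses apically and then
        walks the array backwards;
    ``artifact_detection``
        any node farther than ``radius_mm`` from every electrode.
    """
    pred, gt = _as_points(pred), _as_points(gt)
    labels: set[str] = set()
    if len(pred) == 0:
        return labels
    seq, dmin = _nearest_gt_sequence(pred, gt)

    if np.any(dmin > radius_mm):
        labels.add("artifact_detection")

    on_target = seq[dmin <= radius_mm]
    if on_target.size and np.any(np.bincount(on_target) >= 2):
        labels.add("double_detection")

    running_max = np.maximum.accumulate(seq)
    if np.any(seq[1:] <= running_max[:-1] - 2):
        labels.add("ab_confusion_basal_revisit")

    jumps = np.flatnonzero(np.diff(seq) > 1)
    for j in jumps[jumps < max(2, len(seq) // 2)]:
        tail = seq[j + 1 :]
        if len(tail) >= 3 and np.all(np.diff(tail) <= 0) and tail[-1] < tail[0]:
            labels.add("ab_confusion_reversal")
            break
    return labels


@dataclass
class EvalReport:
    """Per-case evaluation summary."""

    localization_accuracy: float  # mm, over labels present in the prediction
    detection_rate: float  # percent over all electrodes
    detected: np.ndarray  # per-electrode flags, base to apex
    per_electrode_error: np.ndarray  # mm; NaN for missing labels
    conditional_accuracy: float  # mm over detected electrodes only (NaN if none)
    n_missing: int  # labels absent from an incomplete prediction
    error_labels: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "localization_accuracy_mm": self.localization_accuracy,
            "detection_rate_pct": self.detection_rate,
            "conditional_accuracy_mm": self.conditional_accuracy,
            "n_missing": self.n_missing,
            "detected": [bool(f) for f in self.detected],
            "per_electrode_error_mm": [
                None if np.isnan(e) else float(e) for e in self.per_electrode_error
            ],
            "error_labels": sorted(self.error_labels),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate(pred, gt, radius_mm: float = DETECTION_RADIUS_MM) -> EvalReport:
    """Full per-case report: accuracy, detection, error classification."""
    pred, gt = _as_points(pred), _as_points(gt)
    errs = _paired_errors(pred, gt)
    full = np.full(len(gt), np.nan)
    full[: len(errs)] = errs
    rate, flags = detection_rate(pred, gt, radius_mm)
    cond = float(errs[errs <= radius_mm].mean()) if np.any(errs <= radius_mm) else float("nan")
    return EvalReport(
        localization_accuracy=float(errs.mean()) if errs.size else float("nan"),
        detection_rate=rate,
        detected=flags,
        per_electrode_error=full,
        conditional_accuracy=cond,
        n_missing=len(gt) - len(pred),
        error_labels=classify_errors(pred, gt, radius_mm),
    )
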