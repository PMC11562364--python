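"""Volumes, coordinate lists, and region-of-interest extraction.

All geometry is expressed in millimetre world coordinates.  A :class:`Volume`
maps 0-based voxel indices to world positions through the voxel-centre
convention ``world = origin + index * spacing``; distances are always computed
in mm so that voxel-denominated rules (e.g. the 0.9 mm = 3 voxel detection
radius at the nominal 0.3 mm CBCT resolution) remain correct for other
spacings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "read_coordinates",
    "write_coordinates",
    "extract_roi",
    "FormatError",
]


class FormatError(RuntimeError):
    """Raised when a volume file cannot be read or its geometry is ambiguous."""


@dataclass
class Volume:
    """A 3D scalar intensity grid with isotropic-or-not voxel spacing.

    Attributes
    ----------
    intensities
        ``(nx, ny, nz)`` float array.
    spacing
        mm per voxel along each axis (strictly positive).
    origin
        World position in mm of voxel index ``(0, 0, 0)`` (voxel centre).
    """

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World mm coordinates of (fractional) voxel indices, shape (..., 3)."""
        return self.origin + np.asarray(idx, dtype=np.float64) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world mm coordinates, shape (..., 3)."""
        return (np.asarray(xyz, dtype=np.float64) - self.origin) / self.spacing

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Whether world points fall inside the voxel-index bounding box."""
        idx = self.world_to_index(xyz)
        hi = np.asarray(self.shape) - 1
        return np.all((idx >= 0) & (idx <= hi), axis=-1)


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume.

    Only axis-aligned geometries are accepted; rotated direction matrices
    raise :class:`FormatError` rather than silently dropping the rotation.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    try:
        if suffixes.endswith((".nii", ".nii.gz")):
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj).astype(np.float64)
            affine = img.affine
            rot = affine[:3, :3]
            spacing = np.sqrt((rot**2).sum(axis=0))
            if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6 * max(spacing.max(), 1)):
                raise FormatError(f"{path}: non-axis-aligned NIfTI affine is not supported")
            # nibabel affines may carry negative diagonal (flips); reject as ambiguous
            if np.any(np.diag(rot) <= 0):
                raise FormatError(f"{path}: NIfTI affine with axis flips is not supported")
            return Volume(data, spacing, affine[:3, 3].copy())
        if suffixes.endswith(".nrrd"):
            import SimpleITK as sitk

            img = sitk.ReadImage(str(path))
            direction = np.asarray(img.GetDirection()).reshape(3, 3)
            if not np.allclose(direction, np.eye(3), atol=1e-6):
                raise FormatError(f"{path}: non-identity NRRD direction is not supported")
            # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
            data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
            return Volume(data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()))
        raise FormatError(f"{path}: unsupported volume format (use .nii, .nii.gz or .nrrd)")
    except FormatError:
        raise
    except Exception as exc:  # truncated/corrupt files must not pass silently
        raise FormatError(f"{path}: failed to read volume ({exc})") from exc


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI or NRRD, preserving spacing and origin."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(vol.spacing)
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.intensities, affine), str(path))
    elif suffixes.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.intensities.transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"{path}: unsupported volume format (use .nii, .nii.gz or .nrrd)")


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read electrode coordinates (CSV ``electrode,x_mm,y_mm,z_mm`` or JSON).

    Returns a DataFrame indexed 1..L from the base, sorted by electrode label.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        rows = payload["electrodes"] if isinstance(payload, dict) else payload
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    needed = {"electrode", "x_mm", "y_mm", "z_mm"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}, got {list(df.columns)}")
    return df.sort_values("electrode").reset_index(drop=True)


def write_coordinates(positions: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Write base-to-apex electrode positions as CSV or (with metadata) JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    positions = np.asarray(positions, dtype=float)
    df = pd.DataFrame(
        {
            "electrode": np.arange(1, len(positions) + 1),
            "x_mm": positions[:, 0],
            "y_mm": positions[:, 1],
            "z_mm": positions[:, 2],
        }
    )
    if path.suffix == ".json":
        payload = dict(meta or {})
        payload["electrodes"] = df.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2))
    else:
        df.to_csv(path, index=False)


def coordinates_to_array(df: pd.DataFrame) -> np.ndarray:
    """``(L, 3)`` mm array from a coordinate DataFrame, base to apex."""
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


def extract_roi(vol: Volume, gt_positions: np.ndarray, margin_mm: float = 3.0) -> Volume:
    """Crop an axis-aligned region of interest around the electrode array.

    Every face of the returned sub-volume is at least ``margin_mm`` from every
    ground-truth point (per-face margin, clipped at the volume bounds with a
    warning).  The origin is updated so world coordinates are unchanged.
    """
    gt_positions = np.atleast_2d(np.asarray(gt_positions, dtype=float))
    if gt_positions.size == 0:
        raise ValueError("extract_roi needs at least one ground-truth point")
    lo_mm = gt_positions.min(axis=0) - margin_mm
    hi_mm = gt_positions.max(axis=0) + margin_mm
    lo_idx = np.floor(vol.world_to_index(lo_mm)).astype(int)
    hi_idx = np.ceil(vol.world_to_index(hi_mm)).astype(int)
    shape = np.asarray(vol.shape)
    if np.any(lo_idx < 0) or np.any(hi_idx > shape - 1):
        warnings.warn("ROI clipped at volume bounds; margin not met on all faces")
    lo_idx = np.clip(lo_idx, 0, shape - 1)
    hi_idx = np.clip(hi_idx, 0, shape - 1)
    sl = tuple(slice(lo, hi + 1) for lo, hi in zip(lo_idx, hi_idx))
    return Volume(
        vol.intensities[sl].copy(),
        vol.spacing.copy(),
        vol.index_to_world(lo_idx),
    )
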