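"""Synthetic CBCT-like phantoms of implanted cochlear electrode arrays.

A phantom is a 3D intensity volume containing bright, blob-like metal
artifacts at known electrode positions along a decaying helix (the cochlear
spiral), optionally with reduced apical intensity (emulating the single
apical contacts of the MED-EL Flex designs), background noise, and distractor
structures (bone, wire lead).  The generator exists to make every stage of
the localization pipeline testable with exact ground truth, and in
particular to reproduce the geometric regime — inter-electrode spacing
comparable to the separation between adjacent spiral turns, insertion deeper
than one full turn — in which apical–basal confusion arises.

Three presets are shipped:

``clean``
    Well-separated turns (adjacent-turn distance beyond twice the electrode
    spacing), full-intensity contacts, no noise, no distractors.  The
    control condition on which localization should be essentially perfect.
``confusion``
    MED-EL-like wide spacing, insertion angle past 360 degrees,
    adjacent-turn separation comparable to the spacing, strongly dimmed
    apical contacts and moderate noise.  With the preset's candidate
    threshold, apical contacts frequently produce no candidates, so a
    baseline path search walks back onto already-visited basal electrodes.
``artifacts``
    The clean geometry plus a moderate-intensity bone slab and a bright
    wire lead exiting the array basally.

Intensities use a Hounsfield-like scale: background 0, electrode blob peak
2000 (so the localization cost normalization by 2000 maps intensities into
[0, 1]), cortical-bone distractor peak 300.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .registry import EASpec, get_spec
from .volume import Volume, write_coordinates, write_volume

__all__ = [
    "SpiralParams",
    "SpiralCurve",
    "RenderParams",
    "GroundTruth",
    "Phantom",
    "make_spiral",
    "place_electrodes",
    "render",
    "add_distractor",
    "BoneSlab",
    "WireLead",
    "make_phantom",
    "write_phantom",
    "PRESETS",
]


@dataclass(frozen=True)
class SpiralParams:
    """Geometry of a decaying helix standing in for the cochlear duct.

    The curve is ``p(t) = center + (r(t)·cos(a0+t), r(t)·sin(a0+t),
    pitch·t)`` with ``r(t) = base_radius · radius_decay**t`` and ``t`` the
    turning angle in radians from the basal end.
    """

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    base_radius: float = 4.2
    radius_decay: float = 0.96  # per-radian shrink factor
    pitch: float = 0.27  # mm height gain per radian
    total_angle: float = 720.0  # degrees available
    start_angle: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.total_angle <= 0:
            raise ValueError("total_angle must be positive")
        if not 0 < self.radius_decay <= 1:
            raise ValueError("radius_decay must lie in (0, 1]")


class SpiralCurve:
    """Arc-length-parameterized helix built from :class:`SpiralParams`.

    Arc length is accumulated on a dense angular grid (chord summation at
    ~3.5e-4 rad steps, accurate to well under 0.01 mm over two turns) and
    inverted by monotone interpolation.
    """

    def __init__(self, params: SpiralParams, samples_per_degree: int = 50):
        self.params = params
        n = max(4096, int(params.total_angle * samples_per_degree))
        self._theta = np.linspace(0.0, math.radians(params.total_angle), n)
        pts = self._point_at_theta(self._theta)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self._arc = np.concatenate([[0.0], np.cumsum(seg)])

    def _point_at_theta(self, theta: np.ndarray) -> np.ndarray:
        p = self.params
        theta = np.asarray(theta, dtype=float)
        r = p.base_radius * p.radius_decay**theta
        a = math.radians(p.start_angle) + theta
        out = np.stack(
            [r * np.cos(a), r * np.sin(a), p.pitch * theta], axis=-1
        )
        return out + np.asarray(p.center)

    @property
    def total_length(self) -> float:
        """Arc length in mm of the full curve."""
        return float(self._arc[-1])

    def theta_at(self, s) -> np.ndarray:
        """Turning angle (radians from the basal end) at arc length ``s``."""
        s = np.asarray(s, dtype=float)
        if np.any(s < -1e-9) or np.any(s > self.total_length + 1e-9):
            raise ValueError(
                f"arc length outside [0, {self.total_length:.2f}] mm requested"
            )
        return np.interp(s, self._arc, self._theta)

    def point_at(self, s) -> np.ndarray:
        """World position(s) in mm at arc length ``s`` from the basal end."""
        return self._point_at_theta(self.theta_at(s))

    def angle_at(self, s) -> np.ndarray:
        """Insertion angle in degrees at arc length ``s``."""
        return np.degrees(self.theta_at(s))


def make_spiral(params: SpiralParams) -> SpiralCurve:
    """Build the arc-length-parameterized spiral curve."""
    return SpiralCurve(params)


@dataclass
class GroundTruth:
    """Known electrode positions of a phantom, ordered base to apex."""

    positions: np.ndarray  # (L, 3) mm
    insertion_angle: float  # degrees at the most apical contact
    spec_name: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)

    @property
    def n_electrodes(self) -> int:
        return len(self.positions)

    @property
    def seed(self) -> np.ndarray:
        """The most basal electrode position (the path-search seed)."""
        return self.positions[0]


def place_electrodes(
    curve: SpiralCurve, spec: EASpec, arc_offset: float = 2.0
) -> GroundTruth:
    """Place an array's contacts along the curve at the spec's gap distances.

    Electrode 1 (most basal) sits at arc length ``arc_offset`` from the
    curve's basal end; successive contacts follow at cumulative arc lengths
    given by the base-to-apex gap sequence, so the chain ends with the most
    apical contact at ``arc_offset + sum(gaps)``.  Chord distances equal the
    arc-length gaps to within the curvature-dependent chord/arc shortening
    (< 2 % for the shipped presets).
    """
    gaps_base_to_apex = spec.gap_distances[::-1]
    needed = arc_offset + sum(gaps_base_to_apex)
    if needed > curve.total_length:
        raise ValueError(
            f"curve too short: need {needed:.2f} mm of arc "
            f"(offset {arc_offset:.2f} + span {spec.total_span:.2f}), "
            f"have {curve.total_length:.2f} mm"
        )
    s = arc_offset + np.concatenate([[0.0], np.cumsum(gaps_base_to_apex)])
    return GroundTruth(
        positions=curve.point_at(s),
        insertion_angle=float(curve.angle_at(s[-1])),
        spec_name=spec.name,
    )


@dataclass(frozen=True)
class RenderParams:
    """Imaging model of the phantom renderer.

    The metal artifact of each contact is an isotropic Gaussian blob
    (``psf_sigma``); the ``apical_low_intensity_count`` most apical contacts
    of the spec are scaled by ``apical_peak_factor``; Gaussian noise is added
    and the result clipped at zero.
    """

    voxel_spacing: float = 0.3  # mm, isotropic
    psf_sigma: float = 0.45  # mm
    electrode_peak: float = 2000.0
    apical_peak_factor: float = 1.0
    noise_sigma: float = 0.0
    background_level: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_spacing <= 0 or self.psf_sigma <= 0:
            raise ValueError("voxel_spacing and psf_sigma must be positive")
        if not 0 < self.apical_peak_factor <= 1:
            raise ValueError("apical_peak_factor must lie in (0, 1]")


def _add_gaussian_blob(
    arr: np.ndarray, vol: Volume, center: np.ndarray, peak: float, sigma: float
) -> None:
    """Add ``peak * exp(-d^2 / (2 sigma^2))`` around ``center`` (mm) in place."""
    half = 4.0 * sigma
    lo = np.floor(vol.world_to_index(center - half)).astype(int)
    hi = np.ceil(vol.world_to_index(center + half)).astype(int)
    lo = np.clip(lo, 0, np.asarray(arr.shape) - 1)
    hi = np.clip(hi, 0, np.asarray(arr.shape) - 1)
    ix, iy, iz = (np.arange(lo[d], hi[d] + 1) for d in range(3))
    xx = vol.origin[0] + ix * vol.spacing[0] - center[0]
    yy = vol.origin[1] + iy * vol.spacing[1] - center[1]
    zz = vol.origin[2] + iz * vol.spacing[2] - center[2]
    d2 = (
        xx[:, None, None] ** 2 + yy[None, :, None] ** 2 + zz[None, None, :] ** 2
    )
    arr[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += peak * np.exp(
        -d2 / (2.0 * sigma**2)
    )


@dataclass(frozen=True)
class BoneSlab:
    """Moderate-intensity extended block emulating cortical bone."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]  # mm edge lengths
    peak: float = 300.0  # cortical bone reaches ~300 HU in CBCT
    edge_sigma: float = 0.3  # mm of edge smoothing

    def render_into(self, arr: np.ndarray, vol: Volume) -> None:
        center = np.asarray(self.center)
        half = np.asarray(self.size) / 2.0
        lo = np.clip(
            np.floor(vol.world_to_index(center - half)).astype(int),
            0,
            np.asarray(arr.shape) - 1,
        )
        hi = np.clip(
            np.ceil(vol.world_to_index(center + half)).astype(int),
            0,
            np.asarray(arr.shape) - 1,
        )
        block = np.zeros(arr.shape)
        block[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = self.peak
        sig = self.edge_sigma / vol.spacing
        arr += ndimage.gaussian_filter(block, sigma=sig)


@dataclass(frozen=True)
class WireLead:
    """Bright thin curve exiting the array basally (the lead wire)."""

    start: tuple[float, float, float]  # mm, typically the most basal contact
    direction: tuple[float, float, float]  # pointing away from the apex
    length: float = 8.0  # mm
    peak: float = 2000.0
    sigma: float = 0.25  # mm tube radius scale

    def render_into(self, arr: np.ndarray, vol: Volume) -> None:
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        start = np.asarray(self.start, dtype=float)
        # Max (not sum) of overlapping sample blobs keeps the tube peak flat.
        step = min(vol.spacing) / 2.0
        samples = start + d * np.arange(0.0, self.length + step, step)[:, None]
        tube = np.zeros(arr.shape)
        sig = self.sigma
        half = 4.0 * sig
        for c in samples:
            lo = np.clip(
                np.floor(vol.world_to_index(c - half)).astype(int),
                0,
                np.asarray(arr.shape) - 1,
            )
            hi = np.clip(
                np.ceil(vol.world_to_index(c + half)).astype(int),
                0,
                np.asarray(arr.shape) - 1,
            )
            ix, iy, iz = (np.arange(lo[k], hi[k] + 1) for k in range(3))
            d2 = (
                (vol.origin[0] + ix * vol.spacing[0] - c[0])[:, None, None] ** 2
                + (vol.origin[1] + iy * vol.spacing[1] - c[1])[None, :, None] ** 2
                + (vol.origin[2] + iz * vol.spacing[2] - c[2])[None, None, :] ** 2
            )
            region = tube[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
            np.maximum(region, self.peak * np.exp(-d2 / (2 * sig**2)), out=region)
        arr += tube


def add_distractor(kind: str, **params):
    """Construct a distractor by name (``bone_slab`` or ``wire_lead``)."""
    kinds = {"bone_slab": BoneSlab, "wire_lead": WireLead}
    if kind not in kinds:
        raise ValueError(f"unknown distractor kind {kind!r}; choose from {sorted(kinds)}")
    return kinds[kind](**params)


def render(
    gt: GroundTruth,
    spec: EASpec,
    rp: RenderParams = RenderParams(),
    distractors: tuple = (),
    margin_mm: float = 4.0,
) -> Volume:
    """Render a phantom volume around the ground-truth electrode positions.

    The volume is ``background + sum of electrode blobs + distractors``, plus
    seeded Gaussian noise clipped at zero.  The grid covers the electrode
    bounding box with ``margin_mm`` on every face (must be >= 3 mm so the
    ROI-extraction margin fits), voxel-centre aligned.
    """
    if margin_mm < 3.0:
        raise ValueError("margin_mm must be >= 3 mm")
    lo = gt.positions.min(axis=0) - margin_mm
    hi = gt.positions.max(axis=0) + margin_mm
    shape = np.ceil((hi - lo) / rp.voxel_spacing).astype(int) + 1
    vol = Volume(
        np.zeros(shape), np.full(3, rp.voxel_spacing), lo
    )
    arr = vol.intensities
    arr += rp.background_level

    n_dim = min(spec.apical_low_intensity_count, gt.n_electrodes)
    for i, pos in enumerate(gt.positions):  # i = 0 is the most basal contact
        peak = rp.electrode_peak
        if n_dim and i >= gt.n_electrodes - n_dim:
            peak *= rp.apical_peak_factor
        _add_gaussian_blob(arr, vol, pos, peak, rp.psf_sigma)

    for dist in distractors:
        dist.render_into(arr, vol)

    if rp.noise_sigma > 0:
        rng = np.random.default_rng(rp.rng_seed)
        arr += rng.normal(0.0, rp.noise_sigma, size=arr.shape)
        np.clip(arr, 0.0, None, out=arr)
    return vol


# ---------------------------------------------------------------------------
# Shipped presets
# ---------------------------------------------------------------------------


@dataclass
class Phantom:
    """A rendered phantom together with its ground truth and provenance."""

    volume: Volume
    gt: GroundTruth
    spec: EASpec
    alpha1: float  # candidate threshold (percent) recommended for this preset
    preset: str
    render_params: RenderParams
    distractors: tuple = ()


def _per_turn(decay_per_turn: float) -> float:
    """Per-radian shrink factor from a per-turn one."""
    return float(decay_per_turn ** (1.0 / (2.0 * math.pi)))


def _clean_spiral(spec: EASpec) -> SpiralParams:
    # Turns separated by 2.5x the widest gap: adjacent-turn distances fall
    # outside the (d/2, 2d) child-node window, so no cross-turn shortcuts.
    g = max(spec.gap_distances)
    return SpiralParams(
        base_radius=max(3.0, 1.8 * g),
        radius_decay=_per_turn(0.92),
        pitch=2.5 * g / (2.0 * math.pi),
        total_angle=1080.0,
    )


def _confusion_spiral(spec: EASpec) -> SpiralParams:
    # Tightly stacked turns: separation ~ one inter-electrode gap, insertion
    # past 360 degrees — the regime in which a path search can cross turns.
    g = max(spec.gap_distances)
    return SpiralParams(
        base_radius=2.0 * g,
        radius_decay=_per_turn(0.78),
        pitch=1.7 / (2.0 * math.pi) * (g / 2.1),
        total_angle=900.0,
    )


PRESETS = ("clean", "confusion", "artifacts")


def make_phantom(
    preset: str,
    spec_name: str | None = None,
    seed: int = 0,
    noise_sigma: float | None = None,
) -> Phantom:
    """Build one of the shipped phantom presets.

    Parameters
    ----------
    preset
        ``clean``, ``confusion`` or ``artifacts`` (see module docstring).
    spec_name
        Electrode array to simulate; defaults to ``Flex 24`` (clean,
        artifacts) or ``Flex 28`` (confusion).
    seed
        Noise seed; phantoms are bit-identical for identical seeds.
    noise_sigma
        Override the preset's noise level (intensity units).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if spec_name is None:
        spec_name = "Flex 28" if preset == "confusion" else "Flex 24"
    spec = get_spec(spec_name)

    if preset == "confusion":
        spiral = _confusion_spiral(spec)
        rp = RenderParams(
            apical_peak_factor=0.30 if spec.apical_low_intensity_count else 1.0,
            noise_sigma=40.0 if noise_sigma is None else noise_sigma,
            rng_seed=seed,
        )
        alpha1 = 0.30
        distractors: tuple = ()
    else:
        spiral = _clean_spiral(spec)
        rp = RenderParams(
            noise_sigma=(0.0 if preset == "clean" else 30.0)
            if noise_sigma is None
            else noise_sigma,
            rng_seed=seed,
        )
        alpha1 = 1.0
        distractors = ()

    curve = make_spiral(spiral)
    gt = place_electrodes(curve, spec, arc_offset=2.0)

    if preset == "artifacts":
        basal = gt.positions[0]
        away = basal - gt.positions[1]
        away = away / np.linalg.norm(away)
        centroid = gt.positions.mean(axis=0)
        distractors = (
            BoneSlab(
                center=tuple(centroid + np.array([0.0, 0.0, -2.5])),
                size=(10.0, 10.0, 1.5),
            ),
            WireLead(start=tuple(basal), direction=tuple(away), length=6.0),
        )

    vol = render(gt, spec, rp, distractors=distractors)
    return Phantom(
        volume=vol,
        gt=gt,
        spec=spec,
        alpha1=alpha1,
        preset=preset,
        render_params=rp,
        distractors=distractors,
    )


def write_phantom(ph: Phantom, outdir: str | Path, fmt: str = "nii.gz") -> None:
    """Write a phantom's volume (NIfTI/NRRD), ground-truth CSV and JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(ph.volume, outdir / f"phantom.{fmt}")
    write_coordinates(ph.gt.positions, outdir / "gt.csv")
    meta = {
        "spec": ph.spec.name,
        "preset": ph.preset,
        "insertion_angle_deg": ph.gt.insertion_angle,
        "alpha1_pct": ph.alpha1,
        "rng_seed": ph.render_params.rng_seed,
    }
    write_coordinates(ph.gt.positions, outdir / "gt.json", meta=meta)
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
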