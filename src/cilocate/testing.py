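"""Small synthetic inputs for tests, examples and validation scripts."""

from __future__ import annotations

import numpy as np

from .candidates import CandidateSet
from .registry import EASpec
from .volume import Volume

__all__ = ["toy_spec", "StraightCurve", "random_chain_instance", "make_blob_volume"]


def toy_spec(n_electrodes: int, gap: float = 1.0, name: str = "toy") -> EASpec:
    """Minimal constant-spacing array for algorithm-level tests."""
    return EASpec(
        name=name,
        manufacturer="test",
        n_electrodes=n_electrodes,
        gap_distances=(gap,) * (n_electrodes - 1),
    )


class StraightCurve:
    """Degenerate 'spiral': a straight line, where chord equals arc exactly."""

    def __init__(self, origin=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0), length=100.0):
        self.origin = np.asarray(origin, float)
        d = np.asarray(direction, float)
        self.direction = d / np.linalg.norm(d)
        self.total_length = float(length)

    def point_at(self, s):
        s = np.asarray(s, float)
        return self.origin + s[..., None] * self.direction

    def angle_at(self, s):
        return np.zeros_like(np.asarray(s, float))


def random_chain_instance(rng: np.random.Generator, n_electrodes: int, gap: float = 1.0):
    """A small pathfinding instance: jittered true chain plus decoy candidates.

    Returns ``(candidate set, seed position, spec)``.  The true chain follows
    a gently curved polyline at roughly the right gaps so complete chains are
    usually feasible; decoys land nearby, some inside the child-node window.
    """
    spec = toy_spec(n_electrodes, gap)
    seed = rng.uniform(-1, 1, 3)
    direction = np.array([1.0, 0.0, 0.0])
    chain = [seed]
    for _ in range(n_electrodes - 1):
        bend = rng.normal(scale=0.15, size=3)
        direction = direction + bend
        direction /= np.linalg.norm(direction)
        step = gap * rng.uniform(0.9, 1.1)
        chain.append(chain[-1] + step * direction)
    chain = np.asarray(chain[1:])  # the seed itself is not a candidate
    n_decoys = rng.integers(2, 12 - len(chain) + 1)
    decoys = seed + rng.uniform(
        -1.5 * gap * n_electrodes, 1.5 * gap * n_electrodes, (n_decoys, 3)
    )
    points = np.vstack([chain, decoys])
    intensities = rng.uniform(500.0, 2000.0, len(points))
    return CandidateSet(points, intensities), seed, spec


def make_blob_volume(
    centers,
    peaks,
    sigma: float = 0.45,
    spacing: float = 0.3,
    margin: float = 3.0,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> Volume:
    """Small analytic Gaussian-blob volume for refinement/candidate tests."""
    centers = np.atleast_2d(np.asarray(centers, float))
    peaks = np.broadcast_to(np.asarray(peaks, float), (len(centers),))
    lo = centers.min(axis=0) - margin
    hi = centers.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    vol = Volume(np.zeros(shape), np.full(3, spacing), lo)
    ix, iy, iz = (np.arange(n) for n in shape)
    xs = lo[0] + ix * spacing
    ys = lo[1] + iy * spacing
    zs = lo[2] + iz * spacing
    for c, p in zip(centers, peaks):
        d2 = (
            (xs - c[0])[:, None, None] ** 2
            + (ys - c[1])[None, :, None] ** 2
            + (zs - c[2])[None, None, :] ** 2
        )
        vol.intensities += p * np.exp(-d2 / (2 * sigma**2))
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        vol.intensities += rng.normal(0, noise_sigma, size=shape)
        np.clip(vol.intensities, 0, None, out=vol.intensities)
    return vol
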