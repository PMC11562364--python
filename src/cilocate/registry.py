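"""Registry of cochlear-implant electrode-array (EA) geometries.

Each array is described by the number of active contacts ``L``, the L-1
inter-electrode gap distances (millimetres, indexed apex-to-base: ``d_1`` is
the gap between the two most apical contacts), an optional non-stimulating
marker contact, and — for the MED-EL Flex designs — the count of apical
contacts that image dimmer than the basal double contacts.

The registry also carries the per-array cumulative-histogram threshold
``alpha_1`` (percent of ROI voxels retained when generating electrode
candidates) together with a single generalized threshold usable for any array.

Built-in specifications ship as a plain-text YAML config
(``data/arrays.yaml``); user-defined arrays load from the same format via
:func:`load_registry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "EASpec",
    "Registry",
    "get_spec",
    "get_threshold",
    "available_arrays",
    "load_registry",
]


@dataclass(frozen=True)
class EASpec:
    """Geometry of one electrode array.

    Parameters
    ----------
    name, manufacturer
        Identifiers as printed on the product sheet.
    n_electrodes
        Number of active (stimulating) contacts, ``L``.
    gap_distances
        ``L - 1`` inter-electrode distances in mm, ordered apex-to-base:
        ``gap_distances[0]`` separates the two most apical contacts.
    n_markers
        Count of non-stimulating marker contacts (0 or 1).
    marker_gap
        Distance in mm from the most basal active contact to the marker,
        or ``None`` when absent/undocumented.
    apical_low_intensity_count
        Number of most-apical contacts rendered/imaged with reduced
        intensity (5 on MED-EL Flex arrays, whose apical contacts are
        single rather than double); 0 otherwise.
    """

    name: str
    manufacturer: str
    n_electrodes: int
    gap_distances: tuple[float, ...]
    n_markers: int = 0
    marker_gap: float | None = None
    apical_low_intensity_count: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 2:
            raise ValueError("an electrode array needs at least 2 contacts")
        if len(self.gap_distances) != self.n_electrodes - 1:
            raise ValueError(
                f"{self.name}: expected {self.n_electrodes - 1} gap distances, "
                f"got {len(self.gap_distances)}"
            )
        if any(g <= 0 for g in self.gap_distances):
            raise ValueError(f"{self.name}: gap distances must be positive")

    @property
    def total_span(self) -> float:
        """Arc length in mm from the most basal to the most apical contact."""
        return float(sum(self.gap_distances))

    def gap_for_extension(self, path_len: int) -> float:
        """Gap in mm used when growing a ``path_len``-node chain by one node.

        The chain is built base-to-apex: node ``k`` is electrode ``k`` counted
        from the base, so the extension from a ``k``-node path crosses the gap
        between base-indexed electrodes ``k`` and ``k+1`` — entry ``L - k`` of
        the apex-to-base gap list (1-based), i.e. index ``L - k - 1``.
        """
        if not 1 <= path_len <= self.n_electrodes - 1:
            raise ValueError(
                f"path length {path_len} cannot be extended on {self.name} "
                f"(L={self.n_electrodes})"
            )
        return self.gap_distances[self.n_electrodes - path_len - 1]

    def with_marker(self) -> "EASpec":
        """Return a spec whose marker participates as an extra basal node.

        The marker is appended basally with gap ``marker_gap``; localization
        then treats it as one more chain node. Only valid when the array has
        a documented marker gap.
        """
        if self.n_markers == 0 or self.marker_gap is None:
            raise ValueError(f"{self.name} has no marker with a documented gap")
        return replace(
            self,
            n_electrodes=self.n_electrodes + 1,
            gap_distances=self.gap_distances + (self.marker_gap,),
            n_markers=0,
            marker_gap=None,
        )

    def to_config(self) -> dict:
        """Serialize to the plain-text registry record format."""
        rec: dict = {
            "name": self.name,
            "manufacturer": self.manufacturer,
            "n_electrodes": self.n_electrodes,
            "n_markers": self.n_markers,
            "gap_distances_mm": [float(g) for g in self.gap_distances],
            "apical_low_intensity_count": self.apical_low_intensity_count,
        }
        if self.marker_gap is not None:
            rec["marker_gap_mm"] = float(self.marker_gap)
        return rec


def _expand_gaps(spacing, n_electrodes: int) -> tuple[float, ...]:
    """Expand a spacing entry into the per-gap apex-to-base distance list.

    A scalar spacing yields ``L - 1`` equal gaps.  A two-element
    ``[apical, basal]`` range is expanded by linear interpolation from the
    apical extreme to the basal extreme, following the perimodiolar design
    trend of tighter spacing toward the apex.
    """
    n_gaps = n_electrodes - 1
    if np.isscalar(spacing):
        return (float(spacing),) * n_gaps
    lo_apical, hi_basal = float(spacing[0]), float(spacing[1])
    return tuple(np.linspace(lo_apical, hi_basal, n_gaps).tolist())


def _spec_from_record(rec: dict) -> EASpec:
    if "gap_distances_mm" in rec:
        gaps = tuple(float(g) for g in rec["gap_distances_mm"])
    else:
        gaps = _expand_gaps(rec["spacing_mm"], rec["n_electrodes"])
    return EASpec(
        name=rec["name"],
        manufacturer=rec["manufacturer"],
        n_electrodes=int(rec["n_electrodes"]),
        gap_distances=gaps,
        n_markers=int(rec.get("n_markers", 0)),
        marker_gap=(
            float(rec["marker_gap_mm"]) if rec.get("marker_gap_mm") is not None else None
        ),
        apical_low_intensity_count=int(rec.get("apical_low_intensity_count", 0)),
    )


@dataclass
class Registry:
    """A named collection of :class:`EASpec` plus candidate thresholds."""

    specs: dict[str, EASpec] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    generalized_threshold: float = 2.66

    def get_spec(self, name: str) -> EASpec:
        try:
            return self.specs[name]
        except KeyError:
            raise KeyError(
                f"unknown electrode array {name!r}; available: "
                f"{sorted(self.specs)}"
            ) from None

    def get_threshold(self, name: str, mode: str = "individual") -> float:
        """Cumulative-histogram threshold ``alpha_1`` in percent.

        ``mode='individual'`` returns the per-array value; ``'generalized'``
        returns the array-independent threshold.
        """
        if mode == "generalized":
            return self.generalized_threshold
        if mode != "individual":
            raise ValueError(f"mode must be 'individual' or 'generalized', got {mode!r}")
        if name not in self.thresholds:
            raise KeyError(
                f"no individual threshold for {name!r}; available: "
                f"{sorted(self.thresholds)}"
            )
        return self.thresholds[name]

    def names(self) -> list[str]:
        return sorted(self.specs)


def load_registry(path: str | Path | None = None) -> Registry:
    """Load a registry from a YAML config; ``None`` loads the built-in one."""
    if path is None:
        text = (resources.files("cilocate") / "data" / "arrays.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    reg = Registry(generalized_threshold=float(cfg.get("generalized_threshold_pct", 2.66)))
    for rec in cfg["arrays"]:
        spec = _spec_from_record(rec)
        reg.specs[spec.name] = spec
        if rec.get("threshold_pct") is not None:
            thr = float(rec["threshold_pct"])
            if not 0 < thr < 100:
                raise ValueError(f"{spec.name}: threshold must be in (0, 100)%")
            reg.thresholds[spec.name] = thr
    return reg


_BUILTIN: Registry | None = None


def _builtin() -> Registry:
    global _BUILTIN
    if _BUILTIN is None:
        _BUILTIN = load_registry()
    return _BUILTIN


def get_spec(name: str) -> EASpec:
    """Look up a built-in electrode-array specification by name."""
    return _builtin().get_spec(name)


def get_threshold(name: str, mode: str = "individual") -> float:
    """Built-in candidate threshold ``alpha_1`` (percent) for an array."""
    return _builtin().get_threshold(name, mode)


def available_arrays() -> list[str]:
    """Names of the built-in electrode arrays."""
    return _builtin().names()
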