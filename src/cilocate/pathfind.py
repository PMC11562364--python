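"""Beam-search localization of the electrode chain over candidate points.

Starting from a seed node at the most basal electrode, the search grows
paths one node per level until the chain has as many nodes as the array has
contacts.  A child candidate must lie inside a distance window around the
last node — strictly between half and twice the expected inter-electrode
gap — and is scored by

* an intensity cost ``C_I = (I_max - I(c)) / 2000``, relaxed by a factor
  ``alpha_3`` once the path is ``alpha_4`` nodes long (apical contacts image
  dimmer),
* a shape cost ``C_S``: a smoothing term charging sharp bends plus an
  asymmetric penalty on the deviation ``Dst = ||c - p_i|| - d_i`` of the
  step length from the expected gap (undershoot weighted ``alpha_6``,
  overshoot ``alpha_7``); the very first extension instead uses the signed
  deviation ``||c - p_1|| - d_1`` alone,
* in the ``advanced`` variant, a redetection cost ``C_R`` that is infinite
  whenever the candidate comes closer than ``alpha_12`` (two thirds of the
  local gap) to *any* node already in the path, and zero otherwise.  This
  forbids double detection and the apical–basal turn-crossing confusions it
  enables, at no anatomical prior knowledge.

Costs accumulate additively along the path; after each level only the
``P`` cheapest partial paths survive (stable tie-break by insertion order).
The cheapest complete path is returned; if no complete path exists the
longest one found is returned flagged incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import CandidateSet
from .registry import EASpec

__all__ = [
    "CostParams",
    "ElectrodePath",
    "cost_intensity",
    "cost_shape_initial",
    "bend_cosine",
    "cost_shape",
    "cost_redetect",
    "expand_children",
    "find_path",
    "exhaustive_min_path",
]

_INF = float("inf")


@dataclass(frozen=True)
class CostParams:
    """Tunable constants of the path-search cost model.

    Defaults follow the published parameterization: ``alpha3=0.1`` /
    ``alpha4=14`` (intensity relaxation), ``alpha5=1.0`` / ``alpha6=5.2`` /
    ``alpha7=2.0`` (shape), beam width ``P=10``, intensity normalization
    2000, and ``alpha12`` = 2/3 of the local gap unless fixed explicitly.

    ``smoothing_variant`` selects how the bend term is computed:
    ``penalize_bends`` (default) charges ``alpha5 * (1 - X)`` with
    ``X = Cos`` for ``Cos < 0.5`` else ``1`` — zero for a gentle
    continuation, up to ``2*alpha5`` for a reversal, honouring the stated
    contract that sharp bends are expensive.  ``as_printed`` evaluates the
    literal formula ``alpha5 - (1 - X)``, which rewards bends; it is kept
    selectable for fidelity experiments.
    """

    alpha3: float = 0.1
    alpha4: int = 14
    alpha5: float = 1.0
    alpha6: float = 5.2
    alpha7: float = 2.0
    alpha12: float | None = None  # mm; None -> alpha12_fraction * local gap
    alpha12_fraction: float = 2.0 / 3.0
    beam_width: int = 10
    intensity_norm: float = 2000.0
    smoothing_variant: str = "penalize_bends"  # or "as_printed"
    cost_variant: str = "baseline"  # or "advanced"

    def __post_init__(self) -> None:
        if self.beam_width < 1:
            raise ValueError("beam width must be >= 1")
        if self.intensity_norm <= 0:
            raise ValueError("intensity_norm must be positive")
        if self.smoothing_variant not in ("penalize_bends", "as_printed"):
            raise ValueError(f"unknown smoothing_variant {self.smoothing_variant!r}")
        if self.cost_variant not in ("baseline", "advanced"):
            raise ValueError(f"unknown cost_variant {self.cost_variant!r}")

    def alpha12_for_gap(self, gap: float) -> float:
        return self.alpha12 if self.alpha12 is not None else self.alpha12_fraction * gap


@dataclass
class ElectrodePath:
    """An ordered chain of node positions from base to apex.

    ``nodes[0]`` is the seed (most basal electrode).  ``step_costs`` holds
    one ``(C_I, C_S, C_R)`` triple per extension.  ``candidate_indices``
    maps nodes back into the candidate set (-1 for the seed).
    """

    nodes: np.ndarray  # (k, 3) mm
    total_cost: float = 0.0
    step_costs: list[tuple[float, float, float]] = field(default_factory=list)
    candidate_indices: list[int] = field(default_factory=list)
    complete: bool = True

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.nodes)

    def min_pairwise_distance(self) -> float:
        """Smallest distance between any two distinct nodes."""
        if len(self.nodes) < 2:
            return _INF
        d = np.linalg.norm(self.nodes[:, None] - self.nodes[None, :], axis=-1)
        return float(d[np.triu_indices(len(self.nodes), k=1)].min())


# ---------------------------------------------------------------------------
# Cost terms (scalar contracts; the search uses vectorized equivalents)
# ---------------------------------------------------------------------------


def cost_intensity(intensity: float, path_len: int, i_max: float, params: CostParams) -> float:
    """Intensity cost ``(I_max - I(c)) / norm``, relaxed for long paths.

    ``path_len`` is the number of nodes already in the path; once it reaches
    ``alpha_4`` the cost is scaled by ``alpha_3`` so that dim apical contacts
    are not priced out.
    """
    scale = params.alpha3 if path_len >= params.alpha4 else 1.0
    return (i_max - intensity) / params.intensity_norm * scale


def cost_shape_initial(c: np.ndarray, p1: np.ndarray, d1: float) -> float:
    """Signed deviation of the first step length from the first gap."""
    if d1 <= 0:
        raise ValueError("gap distance must be positive")
    return float(np.linalg.norm(np.asarray(c, float) - np.asarray(p1, float)) - d1)


def bend_cosine(c: np.ndarray, p_i: np.ndarray, p_im1: np.ndarray) -> float:
    """Cosine of the turning angle at ``p_i`` when appending ``c``.

    1 means collinear continuation, 0 a right angle, -1 a reversal.
    """
    v1 = np.asarray(c, float) - np.asarray(p_i, float)
    v0 = np.asarray(p_i, float) - np.asarray(p_im1, float)
    n1, n0 = np.linalg.norm(v1), np.linalg.norm(v0)
    if n1 == 0 or n0 == 0:
        raise ValueError("bend cosine undefined for zero-length segments")
    return float(np.dot(v1, v0) / (n1 * n0))


def _smoothing(cos: float, params: CostParams) -> float:
    x = cos if cos < 0.5 else 1.0
    if params.smoothing_variant == "penalize_bends":
        return params.alpha5 * (1.0 - x)
    return params.alpha5 - (1.0 - x)  # literal published formula


def _distance_term(dst: float, params: CostParams) -> float:
    return -params.alpha6 * dst if dst < 0 else params.alpha7 * dst


def cost_shape(c: np.ndarray, path_nodes: np.ndarray, d_i: float, params: CostParams) -> float:
    """Shape cost: bend smoothing plus asymmetric gap-deviation penalty.

    With fewer than two path nodes the smoothing term is skipped and only
    the distance term applies.
    """
    path_nodes = np.atleast_2d(path_nodes)
    dst = float(np.linalg.norm(np.asarray(c, float) - path_nodes[-1]) - d_i)
    term = _distance_term(dst, params)
    if len(path_nodes) >= 2:
        term += _smoothing(bend_cosine(c, path_nodes[-1], path_nodes[-2]), params)
    return term


def cost_redetect(c: np.ndarray, path_nodes: np.ndarray, alpha12: float) -> float:
    """0 if ``c`` keeps clear of every path node by more than ``alpha12``, else inf."""
    path_nodes = np.atleast_2d(path_nodes)
    diff_min = float(np.linalg.norm(path_nodes - np.asarray(c, float), axis=1).min())
    return 0.0 if diff_min > alpha12 else _INF


def expand_children(
    candidates: CandidateSet, path_nodes: np.ndarray, d_i: float
) -> np.ndarray:
    """Indices of candidates eligible to extend the path.

    Eligible means strictly inside the window ``d_i/2 < ||p_i - c|| < 2*d_i``
    around the last node and not exactly coincident with any existing node
    (candidates are discrete voxel centres, so coincidence is exact equality).
    """
    path_nodes = np.atleast_2d(path_nodes)
    dist = np.linalg.norm(candidates.points - path_nodes[-1], axis=1)
    elig = (dist > d_i / 2.0) & (dist < 2.0 * d_i)
    if elig.any():
        coincident = (
            (candidates.points[:, None, :] == path_nodes[None, :, :]).all(axis=2).any(axis=1)
        )
        elig &= ~coincident
    return np.nonzero(elig)[0]


# ---------------------------------------------------------------------------
# Beam search
# ---------------------------------------------------------------------------


def _step_costs_vectorized(
    cand_pts: np.ndarray,
    cand_int: np.ndarray,
    path_nodes: np.ndarray,
    d_i: float,
    i_max: float,
    params: CostParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(C_I, C_S, C_R) arrays for a batch of children of one path."""
    k = len(path_nodes)
    scale = params.alpha3 if k >= params.alpha4 else 1.0
    c_i = (i_max - cand_int) / params.intensity_norm * scale

    last = path_nodes[-1]
    v1 = cand_pts - last
    dist = np.linalg.norm(v1, axis=1)
    if k == 1:
        c_s = dist - d_i  # initial shape cost, as printed (signed)
    else:
        dst = dist - d_i
        c_s = np.where(dst < 0, -params.alpha6 * dst, params.alpha7 * dst)
        v0 = last - path_nodes[-2]
        n0 = np.linalg.norm(v0)
        cos = (v1 @ v0) / np.maximum(dist * n0, 1e-300)
        x = np.where(cos < 0.5, cos, 1.0)
        if params.smoothing_variant == "penalize_bends":
            c_s = c_s + params.alpha5 * (1.0 - x)
        else:
            c_s = c_s + (params.alpha5 - (1.0 - x))

    if params.cost_variant == "advanced":
        a12 = params.alpha12_for_gap(d_i)
        diff_min = np.linalg.norm(
            cand_pts[:, None, :] - path_nodes[None, :, :], axis=2
        ).min(axis=1)
        c_r = np.where(diff_min > a12, 0.0, _INF)
    else:
        c_r = np.zeros(len(cand_pts))
    return c_i, c_s, c_r


def find_path(
    candidates: CandidateSet,
    seed: np.ndarray,
    spec: EASpec,
    params: CostParams = CostParams(),
    i_max: float | None = None,
) -> ElectrodePath:
    """Locate the electrode chain by beam search over the candidate set.

    Parameters
    ----------
    candidates
        Candidate electrode locations (skeleton voxels with intensities).
    seed
        World position in mm of the most basal electrode; becomes node 1.
    spec
        Electrode-array geometry providing ``L`` and the gap sequence.
    params
        Cost constants, beam width and cost variant.
    i_max
        Maximum ROI intensity for the intensity cost; defaults to the
        brightest candidate.

    Returns the cheapest complete ``L``-node path, or the longest achieved
    path flagged ``complete=False`` when the search dead-ends.
    """
    if len(candidates) == 0:
        return ElectrodePath(np.asarray(seed, float).reshape(1, 3), complete=spec.n_electrodes == 1)
    seed = np.asarray(seed, dtype=float).reshape(3)
    pts = candidates.points
    ints = candidates.intensities
    if i_max is None:
        i_max = float(ints.max())

    # Beam entry: (accumulated cost, candidate index list, step-cost list)
    beams: list[tuple[float, list[int], list[tuple[float, float, float]]]] = [
        (0.0, [], [])
    ]
    for k in range(1, spec.n_electrodes):
        d_i = spec.gap_for_extension(k)
        extensions: list[tuple[float, int, list[int], list[tuple[float, float, float]]]] = []
        order = 0
        for acc, idxs, steps in beams:
            path_nodes = np.vstack([seed[None, :], pts[idxs]]) if idxs else seed[None, :]
            elig = expand_children(candidates, path_nodes, d_i)
            if elig.size == 0:
                continue
            c_i, c_s, c_r = _step_costs_vectorized(
                pts[elig], ints[elig], path_nodes, d_i, i_max, params
            )
            total = c_i + c_s + c_r
            for j, ci in enumerate(elig):
                if not np.isfinite(total[j]):
                    continue  # infinite C_R: extension removed outright
                extensions.append(
                    (
                        acc + float(total[j]),
                        order,
                        idxs + [int(ci)],
                        steps + [(float(c_i[j]), float(c_s[j]), float(c_r[j]))],
                    )
                )
                order += 1
        if not extensions:
            # Dead end: report the cheapest longest partial path.
            acc, idxs, steps = min(beams, key=lambda b: b[0])
            return ElectrodePath(
                np.vstack([seed[None, :], pts[idxs]]) if idxs else seed[None, :],
                total_cost=acc,
                step_costs=steps,
                candidate_indices=[-1] + idxs,
                complete=False,
            )
        extensions.sort(key=lambda e: (e[0], e[1]))  # stable: cost, insertion order
        beams = [(c, i, s) for c, _, i, s in extensions[: params.beam_width]]

    acc, idxs, steps = beams[0]
    return ElectrodePath(
        np.vstack([seed[None, :], pts[idxs]]),
        total_cost=acc,
        step_costs=steps,
        candidate_indices=[-1] + idxs,
        complete=True,
    )


def exhaustive_min_path(
    candidates: CandidateSet,
    seed: np.ndarray,
    spec: EASpec,
    params: CostParams = CostParams(),
    i_max: float | None = None,
) -> ElectrodePath | None:
    """Global minimum-cost chain by depth-first enumeration.

    Enumerates every feasible chain (window, coincidence and — in the
    advanced variant — redetection constraints) and sums the step costs
    afresh along each complete chain.  Exponential in ``L``; intended for
    small instances as the independent check of the beam search.
    Returns ``None`` when no complete chain exists.
    """
    seed = np.asarray(seed, dtype=float).reshape(3)
    pts = candidates.points
    ints = candidates.intensities
    if len(candidates) == 0:
        return None
    if i_max is None:
        i_max = float(ints.max())

    best: list = [None, _INF]

    def recurse(idxs: list[int], acc: float, steps: list) -> None:
        k = len(idxs) + 1
        if k == spec.n_electrodes:
            if acc < best[1]:
                best[0] = (list(idxs), acc, list(steps))
                best[1] = acc
            return
        d_i = spec.gap_for_extension(k)
        path_nodes = np.vstack([seed[None, :], pts[idxs]]) if idxs else seed[None, :]
        for ci in expand_children(candidates, path_nodes, d_i):
            c = pts[ci]
            c_int = cost_intensity(float(ints[ci]), k, i_max, params)
            if k == 1:
                c_shp = cost_shape_initial(c, seed, d_i)
            else:
                c_shp = cost_shape(c, path_nodes, d_i, params)
            if params.cost_variant == "advanced":
                c_red = cost_redetect(c, path_nodes, params.alpha12_for_gap(d_i))
                if not np.isfinite(c_red):
                    continue
            else:
                c_red = 0.0
            recurse(
                idxs + [int(ci)],
                acc + c_int + c_shp + c_red,
                steps + [(c_int, c_shp, c_red)],
            )

    recurse([], 0.0, [])
    if best[0] is None:
        return None
    idxs, acc, steps = best[0]
    return ElectrodePath(
        np.vstack([seed[None, :], pts[idxs]]),
        total_cost=acc,
        step_costs=steps,
        candidate_indices=[-1] + idxs,
        complete=True,
    )
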