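# Methods

## Problem and scope

After cochlear implantation, CBCT imaging shows each electrode contact as a
bright, roughly blob-like metal artifact on an otherwise low-intensity
background (cortical bone reaches ~300 HU; contact artifacts are far
brighter). The task is to recover the ordered chain of `L` contact
positions, base to apex, given the array geometry and the position of the
most basal contact. `cilocate` implements a graph-based chain search for
distantly spaced arrays: candidate generation by thresholding and
skeletonization, beam search under intensity/shape costs with an optional
anti-redetection term, and grid-based sub-voxel refinement. Automatic ROI
segmentation, registration to cochlear anatomy, and learning-based
detection are out of scope; the ROI and the path seed derive from reference
coordinates, as in the evaluation protocol the pipeline follows.

All geometry is in millimetre world coordinates with the voxel-centre
convention `world = origin + index · spacing`. Distances are never counted
in voxels, so voxel-denominated rules (0.9 mm = 3 voxels, 3 mm = 10 voxels)
remain correct at non-nominal spacings (e.g. 0.125 mm scans).

## Candidate generation

The cutoff for the binary mask is the top-quantile reading of the
cumulative-histogram threshold: retain the brightest `α₁` percent of ROI
voxels (ties at the cutoff kept, at least one voxel always retained). The
exact histogram construction of the original method is not published; the
quantile reading reproduces its qualitative behaviour — larger `α₁` keeps
more voxels, with bone entering the mask around `α₁ ≈ 2.4–2.7 %`.

The mask is thinned with 3D medial-axis (Lee) thinning, which preserves
connectivity and line endpoints. One caveat discovered in testing: the
thinning can erode a small compact blob (an isolated contact artifact of
~50 voxels) to *nothing*. Since an isolated blob is precisely a potential
electrode, candidate extraction is component-preserving: any mask component
whose skeleton is empty contributes its brightest voxel instead. Candidates
carry the raw voxel intensity (not interpolated).

The per-array threshold is chosen by sweeping `α₁` over 0.01–3.0 % in
0.01 % steps and computing, for each value, the percentage of electrodes
with at least one candidate within 0.9 mm of the reference position; the
chosen value is the smallest attaining maximum coverage (most selective,
fewest distractor candidates). Identical cutoffs are grouped so the sweep
skeletonizes once per distinct mask.

## Path search

The chain is grown from a seed node fixed at the most basal reference
coordinate. Extending a `k`-node path uses the gap between base-indexed
electrodes `k` and `k+1`; the registry stores gaps apex-to-base (`d₁` is
the most apical gap), matching the indexing convention of the cost model,
and maps between the two. A child must lie strictly inside
`(dᵢ/2, 2·dᵢ)` of the last node (bounds strict as printed) and must not
coincide exactly with an existing node (candidates are discrete voxel
centres, so exact equality is the right coincidence test).

Step costs:

- `C_I = (I_max − I(c))/2000 · (α₃ if i ≥ α₄ else 1)` with `α₃ = 0.1`,
  `α₄ = 14`, `i` the current path length. With 12-contact arrays the
  relaxation never triggers at the default `α₄`; it is configurable, since
  no per-array values are published.
- First extension: `C_S,initial = ‖c − p₁‖ − d₁`, signed as printed (a
  too-close candidate receives negative cost).
- Later extensions: `C_S` = bend term + distance term, the distance term
  being `−α₆·Dst` for undershoot and `α₇·Dst` for overshoot
  (`α₅, α₆, α₇ = 1.0, 5.2, 2.0`).
- Advanced variant only: `C_R = ∞` if `min_i ‖c − pᵢ‖ ≤ α₁₂`, else 0, with
  `α₁₂ = ⅔` of the **local** gap `dᵢ` (for constant-spacing arrays this
  coincides with ⅔ of "the" spacing; deriving it locally covers
  variable-pitch arrays). The strict inequality is honoured: a candidate at
  exactly `α₁₂` is rejected. Infinite cost is implemented by removing the
  extension before accumulation, so no `∞` arithmetic occurs.

**Bend-term variants.** The printed smoothing formula,
`α₅ − (1 − X)` with `X = Cos` for `Cos < 0.5` else `1`, *lowers* the cost
of sharper bends, contradicting its stated purpose (charging sharp bends).
The default `penalize_bends` variant computes `α₅·(1 − X)` — zero for a
gentle continuation, up to `2α₅` for a reversal — honouring the contract;
`as_printed` remains selectable for fidelity experiments.

Costs accumulate additively; after each level the `P = 10` cheapest partial
paths survive, ties broken by insertion order (stable sort), so identical
inputs always produce identical paths. If no extension exists at some
level, the cheapest longest partial path is returned flagged incomplete
rather than raising — evaluation can still count the detected contacts.
With a saturating beam width the search provably equals exhaustive
enumeration of feasible chains; the test suite verifies this on randomized
instances for both cost variants, against an independent depth-first
enumerator.

## Refinement

Around each voxel-level node a cubic grid of `(2α₉+1)³ = 343` offsets is
laid (`α₈ = 0.12 mm` step, integer extents ±`α₉ = 3`; the published grid
notation mixes mm and index units — integer lattice indices scaled by `α₈`,
a ±0.36 mm window, is the reading consistent with the original method).
Beam search over the per-node grids minimizes
`−G_σ(I(c)) + (−α₁₀·Dst if Dst < 0 else α₁₁·Dst)` with `σ = 0.3 mm`,
`α₁₀ = 50`, `α₁₁ = 20`, `Dst` referenced to the previously refined node and
the corresponding gap. The seed node, having no predecessor, is anchored to
its successor's unrefined position. The redetection term is not applied
during refinement: neighbouring grids can only overlap within ⅔ of a gap
for pathological geometries.

`G_σ` is the volume smoothed once with a normalized isotropic Gaussian
(edge-replicated boundaries, so a constant volume responds with the
constant) and sampled with **cubic B-spline interpolation** (coefficients
prefiltered once). Trilinear sampling was tried first and rejected: a
piecewise-linear interpolant has no maxima between voxel centres, so the
blob term cannot pull a node off the voxel lattice and refined errors stay
at ~0.2 mm; with the cubic interpolant the response peaks at the blob
centre wherever it falls, and refined errors on clean phantoms drop to
≤ 0.12 mm (one grid step). No node can move farther than the grid
half-diagonal `α₈·α₉·√3 ≈ 0.62 mm`.

Because the refinement cost couples only consecutive nodes, its exact
minimizer over all grid combinations is computable by dynamic programming;
the suite uses that as the independent oracle for the beam refinement.

## Evaluation

`L_a` is the mean Euclidean error over same-labelled contacts; the
detection radius is 0.9 mm inclusive. For an incomplete chain the missing
labels count as undetected and are excluded from the `L_a` mean but
reported (`n_missing`); conditional accuracy (mean error over detected
contacts only) is reported alongside. Error classes are assigned by
automated nearest-ground-truth sequence heuristics — a reproducible proxy
for what is otherwise manual visual classification: double detection (two
on-target nodes on one contact), basal revisit (the nearest-index sequence
climbs, then falls back by ≥ 2 — a drop of 1 is allowed so that benign
nearest-neighbour jitter is not flagged), reversal (an early forward jump
> 1 followed by a monotone descending tail), artifact detection (a node
> 0.9 mm from every contact).

## Synthetic phantoms

The generator emulates what the localization algorithm actually consumes:
bright Gaussian blobs (peak 2000, PSF σ 0.45 mm) on a zero background at
0.3 mm isotropic voxels, along a decaying helix
`r(t) = r₀·λᵗ, z = pitch·t`; contacts are placed at cumulative arc lengths
equal to the array's gap sequence, with curvature kept gentle enough that
chord distances match gaps to < 2 %. The MED-EL Flex design's dimmer
apical contacts are modelled by scaling the 5 most apical blob peaks;
distractors are a smoothed moderate-intensity slab (bone, peak 300) and a
bright thin tube exiting the array basally (wire lead). Noise is additive
Gaussian, seeded, clipped at zero; rendering is bit-deterministic per seed
and linear in distractors. The intensity scale makes the `/2000`
normalization of the intensity cost map into [0, 1].

Presets:

- **clean** — turns separated by 2.5× the widest gap (outside the
  `(d/2, 2d)` child window), full-intensity contacts, no noise. Control
  condition: candidate coverage and detection are 100 % and refinement
  recovers blob centres to ≤ 0.12 mm for the isolated-blob arrays
  (Flex 28/24/20, SlimJ).
- **confusion** — base radius 2× the spacing, per-turn radius factor 0.78,
  1.7 mm per-turn height gain, insertion ≈ 390° > 360°, adjacent-turn
  separation ≈ one spacing (inside the child window); apical peaks scaled
  to 0.30, noise σ 40, preset threshold `α₁ = 0.30 %`. The threshold sits
  below the dim-apical quantile, so apical contacts often get no
  candidates and the baseline search re-descends onto the basal turn —
  the documented real-data failure mechanism. The geometry satisfies every
  stated precondition of the confusion regime and was calibrated once to
  realize it.
- **artifacts** — the clean geometry plus bone slab and wire lead,
  moderate noise.

What the phantoms do *not* model: beam hardening, streak artifacts,
projection-domain physics, scanner-dependent PSFs, anatomical background
texture, and the merged-contact appearance statistics of real closely
spaced arrays. Passing tests on phantoms therefore demonstrate algorithmic
correctness (search optimality, the anti-redetection guarantee, metric
semantics, sub-voxel recovery under the blob model), not clinical accuracy
figures.

## Numerical and design choices

- Threshold ties: kept above the cutoff; retained count may exceed the
  nominal quantile only by tie multiplicity.
- The candidate-count-vs-`α₁` relation is *not* monotone (thinning is not
  monotone in the mask); what is guaranteed and asserted is monotone mask
  growth, with coverage monotonicity checked empirically per phantom.
- ROI extraction applies the 3 mm margin per face, clipping at volume
  bounds with a warning; world coordinates are invariant under cropping.
- Beam and refinement tie-breaks are stable (cost, then insertion order).
- Range-valued spacings (Hybrid-L 0.6–0.8, CI24RE 0.39–0.81, CI624
  0.824–0.95) expand to per-gap lists by linear interpolation from the
  apical to the basal extreme, following the perimodiolar design trend;
  this is an assumption, as the per-gap values are not published.
- Marker contacts (MidScala, SlimJ, Hybrid-L) are excluded from `L` by
  default; `EASpec.with_marker()` opts a documented marker in as an extra
  basal chain node.
- The experiment battery sizes (a few hundred cases, ROIs of ~70 k voxels)
  are chosen to characterize the regimes fully at desk scale; the paired
  baseline/advanced comparison uses a simple sign test across seeds.

## Known limitations

- Closely spaced arrays (gaps ≤ ~1.2 mm at the 0.45 mm PSF) render as
  merged tubes; chain phase can drift by a contact or more along the tube,
  and per-contact sub-voxel recovery is not meaningful there. This mirrors
  the method's weaker behaviour on such arrays with real data; spline-based
  labelling approaches suit that regime better.
- The advanced variant can dead-end (incomplete chain) when the threshold
  leaves apical contacts without candidates: it refuses to revisit, and
  reports a flagged partial chain. Detection never falls below the
  baseline's in the tested regimes, but the missing contacts are not
  recovered.
- The seed is taken from reference coordinates; automatic basal-contact
  detection is not implemented.
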