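# cilocate

Automatic localization of cochlear-implant (CI) electrode contacts in
postoperative cone-beam CT (CBCT) volumes, for researchers who need
per-contact positions at scale — e.g. to relate electrode placement to
hearing outcomes — without manual labelling by a trained expert.

The package implements a graph-based localization pipeline for distantly
spaced electrode arrays, together with an anti-redetection cost term that
eliminates double detection and the apical–basal confusions that arise when
an array is inserted deeper than one full cochlear turn, plus a synthetic
helical phantom generator that makes every stage testable with exact ground
truth.

## Method

Given a volume, the ground-truth-derived region of interest around the
array, and the array geometry (number of contacts `L`, inter-electrode gaps
`d_i`), the pipeline is:

1. **Candidates.** Keep the brightest `α₁` percent of ROI voxels (cumulative
   histogram threshold), binarize, and thin the mask to its 3D centerline;
   skeleton voxels become candidate electrode positions. `α₁` is chosen per
   array by sweeping 0.01–3 % in 0.01 % steps and taking the smallest value
   that puts a candidate within 0.9 mm of every contact.
2. **Path search.** From a seed at the most basal contact, grow chains one
   node per level by beam search (width `P = 10`). A child `c` must satisfy
   `dᵢ/2 < ‖pᵢ − c‖ < 2·dᵢ` and is scored by

   - intensity cost `C_I = (I_max − I(c))/2000`, relaxed by `α₃ = 0.1` from
     path length `α₄ = 14` on (apical contacts image dimmer);
   - shape cost `C_S`: a bend penalty (zero for a gentle continuation, up to
     `2α₅` for a reversal) plus an asymmetric penalty on
     `Dst = ‖c − pᵢ‖ − dᵢ` (undershoot × `α₆ = 5.2`, overshoot × `α₇ = 2.0`);
   - **redetection cost** `C_R` (the advanced variant): infinite whenever
     `c` comes within `α₁₂ = ⅔·dᵢ` of *any* node already in the path, else
     zero. This structurally forbids detecting a contact twice — and with it
     the turn-crossing confusions — using no anatomical prior.

3. **Refinement.** Each node is refined over a cubic grid of offsets
   (0.12 mm step, ±3 steps per axis) minimizing
   `−G_σ(I(c)) + penalty(Dst)` with a Gaussian blob response of
   `σ = 0.3 mm`, giving sub-voxel positions.

Evaluation follows the field's standard criteria: localization accuracy
`L_a` (mean Euclidean error over same-labelled contacts, mm) and detection
rate (percent of contacts within 0.9 mm = 3 voxels at 0.3 mm resolution),
plus automated classification of the characteristic failure modes (artifact
detection, double detection, apical–basal confusion in either direction).

A registry ships the geometries of ten commercial arrays (MED-EL Flex 16–28,
AB MidScala/SlimJ, Oticon Neuro ZTI EVO, Cochlear Hybrid-L / Nucleus CI24RE
/ CI624) and their per-array candidate thresholds.

## Worked example

`python examples/04_confusion_repair.py` localizes a deep-insertion phantom
(insertion angle 389°, 2.1 mm spacing, dim apical contacts) with both cost
variants; its first case prints

```
seed 0:
  baseline  detection  41.7%  L_a  2.35 mm  min node distance 0.11 mm  errors: ab_confusion_basal_revisit,double_detection
  advanced  detection  58.3%  L_a  0.11 mm  min node distance 1.92 mm  errors: none
```

The baseline chain ascends the array and then re-descends onto the basal
turn, placing two nodes on one contact (its minimum pairwise node distance
collapses to 0.11 mm); the advanced cost keeps all nodes at least ⅔ of the
spacing apart, repairing the confusion and cutting the mean error from
2.35 mm to 0.11 mm. On the well-separated `clean` phantom the full pipeline
detects 12/12 contacts with `L_a` = 0.050 mm and a worst refined error of
0.083 mm — under the 0.12 mm refinement grid step (see
`examples/02_localize_clean.py`).

The `examples/` directory has one short script per capability (phantom
simulation, localization, threshold sweep, confusion repair, experiment
battery); a thin `cilocate` CLI exposes the same steps
(`simulate`, `extract-roi`, `candidates`, `sweep-threshold`, `localize`,
`evaluate`, `battery`).

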