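# Built-in electrode-array specifications and per-array cumulative-histogram
# thresholds (percent of ROI voxels retained).
#
# spacing_mm: scalar for constant-spacing arrays, or [apical, basal] extremes
# for variable-pitch arrays (expanded to per-gap distances by the registry).
# marker_gap_mm: distance from the most basal active electrode to the
# non-stimulating marker contact, where the array has one and the distance is
# documented.
# apical_low_intensity_count: number of most-apical contacts that image dimmer
# (single contacts on the MED-EL Flex designs, vs double contacts basally).

generalized_threshold_pct: 2.66

arrays:
  - name: Flex 28
    manufacturer: MED-EL
    n_electrodes: 12
    n_markers: 0
    spacing_mm: 2.1
    apical_low_intensity_count: 5
    threshold_pct: 0.60
  - name: Flex 24
    manufacturer: MED-EL
    n_electrodes: 12
    n_markers: 0
    spacing_mm: 1.9
    apical_low_intensity_count: 5
    threshold_pct: 0.96
  - name: Flex 20
    manufacturer: MED-EL
    n_electrodes: 12
    n_markers: 0
    spacing_mm: 1.5
    apical_low_intensity_count: 5
    threshold_pct: 0.74
  - name: Flex 16
    manufacturer: MED-EL
    n_electrodes: 12
    n_markers: 0
    spacing_mm: 1.0
    apical_low_intensity_count: 5
    threshold_pct: 2.66
  - name: MidScala
    manufacturer: AB
    n_electrodes: 16
    n_markers: 1
    spacing_mm: 0.975
    marker_gap_mm: 3.0
    apical_low_intensity_count: 0
    threshold_pct: 0.49
  - name: SlimJ
    manufacturer: AB
    n_electrodes: 16
    n_markers: 1
    spacing_mm: 1.3
    marker_gap_mm: 3.0
    apical_low_intensity_count: 0
    threshold_pct: 0.22
  - name: Neuro ZTI EVO
    manufacturer: Oticon
    n_electrodes: 20
    n_markers: 0
    spacing_mm: 1.2
    apical_low_intensity_count: 0
    threshold_pct: 0.20
  - name: Hybrid-L
    manufacturer: Cochlear
    n_electrodes: 22
    n_markers: 1
    spacing_mm: [0.6, 0.8]
    apical_low_intensity_count: 0
    threshold_pct: 2.37
  - name: Nucleus CI24RE (CA)
    manufacturer: Cochlear
    n_electrodes: 22
    n_markers: 0
    spacing_mm: [0.39, 0.81]
    apical_low_intensity_count: 0
    threshold_pct: 0.48
  - name: Nucleus CI624
    manufacturer: Cochlear
    n_electrodes: 22
    n_markers: 0
    spacing_mm: [0.824, 0.95]
    apical_low_intensity_count: 0
    threshold_pct: 0.64
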