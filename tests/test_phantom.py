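"""Spiral geometry, electrode placement, rendering and presets."""

import math

import numpy as np
import pytest

from cilocate.phantom import (
    BoneSlab,
    RenderParams,
    SpiralParams,
    WireLead,
    add_distractor,
    make_phantom,
    make_spiral,
    place_electrodes,
    render,
)
from cilocate.registry import get_spec

from conftest import StraightCurve, toy_spec


class TestSpiral:
    def test_planar_circle_circumference(self):
        r = 3.0
        curve = make_spiral(SpiralParams(base_radius=r, radius_decay=1.0, pitch=0.0, total_angle=360.0))
        assert curve.total_length == pytest.approx(2 * math.pi * r, abs=1e-4)

    def test_half_turn_is_diametrically_opposite(self):
        r = 3.0
        curve = make_spiral(SpiralParams(base_radius=r, radius_decay=1.0, pitch=0.0, total_angle=360.0))
        p0 = curve.point_at(0.0)
        p_half = curve.point_at(3 * math.pi)  # arc length of half a turn
        assert np.linalg.norm(p_half - p0) == pytest.approx(2 * r, abs=1e-3)

    def test_arc_length_matches_fine_quadrature(self):
        """Arc length over two turns agrees with 10x-resolution quadrature."""
        params = SpiralParams(base_radius=4.0, radius_decay=0.96, pitch=0.25, total_angle=720.0)
        curve = make_spiral(params)
        # independent oracle: direct quadrature of ||dp/dt|| at 10x sampling
        k = -math.log(params.radius_decay)
        n = 10 * 50 * 720
        t = np.linspace(0.0, math.radians(720.0), n)
        r = params.base_radius * params.radius_decay**t
        drdt = -k * r
        speed = np.sqrt(r**2 + drdt**2 + params.pitch**2)
        oracle = np.trapezoid(speed, t)
        assert curve.total_length == pytest.approx(oracle, abs=0.01)

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            SpiralParams(base_radius=0.0)
        with pytest.raises(ValueError):
            SpiralParams(radius_decay=1.5)
        with pytest.raises(ValueError):
            SpiralParams(total_angle=-10.0)


class TestPlacement:
    def test_flex24_chords_within_two_percent(self):
        spec = get_spec("Flex 24")
        curve = make_spiral(SpiralParams(base_radius=4.0, radius_decay=0.995, pitch=0.5, total_angle=1080.0))
        gt = place_electrodes(curve, spec, arc_offset=2.0)
        assert gt.n_electrodes == 12
        chords = np.linalg.norm(np.diff(gt.positions, axis=0), axis=1)
        assert chords.shape == (11,)
        assert np.all(np.abs(chords - 1.9) / 1.9 < 0.02)

    def test_straight_line_chords_equal_gaps(self):
        spec = toy_spec(6, gap=1.3)
        gt = place_electrodes(StraightCurve(), spec, arc_offset=5.0)
        chords = np.linalg.norm(np.diff(gt.positions, axis=0), axis=1)
        assert chords == pytest.approx(np.full(5, 1.3), abs=1e-12)

    def test_too_short_curve_reports_required_length(self):
        spec = get_spec("Flex 28")  # span 23.1 mm
        curve = make_spiral(SpiralParams(base_radius=3.0, radius_decay=1.0, pitch=0.0, total_angle=90.0))
        with pytest.raises(ValueError, match="mm"):
            place_electrodes(curve, spec, arc_offset=1.0)

    def test_deep_placement_min_interturn_distance_matches_bruteforce(self):
        """Closest approach between electrode 1 and the deep contacts equals
        the exhaustive pairwise computation."""
        ph = make_phantom("confusion", "Flex 28", seed=0)
        pos = ph.gt.positions
        d = np.linalg.norm(pos[0] - pos[8:], axis=1)
        brute = min(
            math.dist(pos[0], pos[j]) for j in range(9, len(pos))
        )
        assert d[1:].min() == pytest.approx(brute, abs=1e-12)


class TestRender:
    def test_global_max_at_an_electrode(self):
        spec = toy_spec(4, gap=2.0)
        gt = place_electrodes(StraightCurve(), spec, arc_offset=1.0)
        vol = render(gt, spec, RenderParams(noise_sigma=0.0))
        peak_idx = np.unravel_index(np.argmax(vol.intensities), vol.shape)
        peak_mm = vol.index_to_world(np.asarray(peak_idx))
        d = np.linalg.norm(gt.positions - peak_mm, axis=1)
        assert d.min() <= math.sqrt(3) * 0.3  # within one voxel of a centre

    def test_same_seed_bit_identical(self):
        ph1 = make_phantom("confusion", "Flex 24", seed=7)
        ph2 = make_phantom("confusion", "Flex 24", seed=7)
        assert np.array_equal(ph1.volume.intensities, ph2.volume.intensities)
        ph3 = make_phantom("confusion", "Flex 24", seed=8)
        assert not np.array_equal(ph1.volume.intensities, ph3.volume.intensities)

    def test_apical_dimming_factor(self):
        """Apical blob peaks scale by the configured factor."""
        spec = get_spec("Flex 28")  # 5 dim apical contacts
        curve = make_spiral(SpiralParams(base_radius=4.5, radius_decay=0.995, pitch=0.6, total_angle=1080.0))
        gt = place_electrodes(curve, spec, arc_offset=2.0)
        vol = render(gt, spec, RenderParams(apical_peak_factor=0.5, noise_sigma=0.0))
        idx = np.round(vol.world_to_index(gt.positions)).astype(int)
        peaks = vol.intensities[tuple(idx.T)]
        basal = peaks[:7].mean()
        apical = peaks[7:].mean()
        assert apical / basal == pytest.approx(0.5, rel=0.05)

    def test_noise_free_render_is_additive_in_distractors(self):
        spec = toy_spec(3, gap=2.0)
        gt = place_electrodes(StraightCurve(), spec, arc_offset=1.0)
        rp = RenderParams(noise_sigma=0.0)
        slab = BoneSlab(center=(3.0, 1.5, 0.0), size=(2.0, 2.0, 1.0))
        wire = WireLead(start=tuple(gt.positions[0]), direction=(-1.0, 0.0, 0.0), length=2.0)
        both = render(gt, spec, rp, distractors=(slab, wire))
        only_slab = render(gt, spec, rp, distractors=(slab,))
        only_wire = render(gt, spec, rp, distractors=(wire,))
        none = render(gt, spec, rp)
        assert np.allclose(
            both.intensities,
            only_slab.intensities + only_wire.intensities - none.intensities,
            atol=1e-9,
        )

    def test_wire_lead_is_bright_and_connected(self):
        spec = toy_spec(3, gap=2.0)
        gt = place_electrodes(StraightCurve(), spec, arc_offset=1.0)
        wire = add_distractor(
            "wire_lead", start=tuple(gt.positions[0]), direction=(-1.0, 0.0, 0.0), length=2.5
        )
        vol = render(gt, spec, RenderParams(noise_sigma=0.0), distractors=(wire,))
        bare = render(gt, spec, RenderParams(noise_sigma=0.0))
        extra = vol.intensities - bare.intensities
        # bright voxels along the wire, in one connected run
        from scipy import ndimage

        _, n = ndimage.label(extra > 1000.0)
        assert n == 1

    def test_unknown_distractor_kind(self):
        with pytest.raises(ValueError, match="bone_slab"):
            add_distractor("metal_screw", center=(0, 0, 0))


class TestPresets:
    @pytest.mark.parametrize("preset,spec_name", [
        ("clean", "Flex 24"),
        ("clean", "SlimJ"),
        ("confusion", "Flex 28"),
        ("confusion", "Flex 24"),
        ("artifacts", "Flex 24"),
    ])
    def test_chord_error_under_two_percent(self, preset, spec_name):
        ph = make_phantom(preset, spec_name, seed=0)
        chords = np.linalg.norm(np.diff(ph.gt.positions, axis=0), axis=1)
        gaps = np.asarray(ph.spec.gap_distances[::-1])
        assert np.all(np.abs(chords - gaps) / gaps < 0.02)

    def test_confusion_preset_realizes_the_confusion_regime(self):
        """Deep insertion, tight turn stacking, and an inter-turn pair inside
        the child-node distance window — the precondition for apical–basal
        confusion."""
        ph = make_phantom("confusion", "Flex 28", seed=0)
        spacing = max(ph.spec.gap_distances)
        assert spacing >= 1.5
        assert ph.gt.insertion_angle > 360.0
        pos = ph.gt.positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        L = len(pos)
        ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
        interturn = d[np.abs(ii - jj) >= 3]
        # adjacent-turn separation comparable to the spacing
        assert 0.5 * spacing <= interturn.min() <= 2.0 * spacing
        # some inter-turn pair lies strictly inside the (d/2, 2d) window
        assert np.any((interturn > spacing / 2) & (interturn < 2 * spacing))

    def test_clean_preset_has_no_interturn_pair_in_window(self):
        ph = make_phantom("clean", "Flex 24", seed=0)
        spacing = max(ph.spec.gap_distances)
        pos = ph.gt.positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        L = len(pos)
        ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
        interturn = d[np.abs(ii - jj) >= 3]
        assert np.all(interturn >= 2.0 * spacing)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            make_phantom("hardmode")
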