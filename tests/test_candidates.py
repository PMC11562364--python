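"""Cumulative-histogram threshold, mask, thinning and the threshold sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cilocate.candidates import (
    binary_mask,
    candidates_from_roi,
    coverage,
    cumulative_threshold,
    extract_candidates,
    parametrize_threshold,
)
from cilocate.phantom import make_phantom
from cilocate.volume import Volume, extract_roi

from conftest import make_blob_volume


def _vol(arr, spacing=0.3):
    arr = np.asarray(arr, dtype=float)
    return Volume(arr, np.full(3, spacing), np.zeros(3))


class TestCumulativeThreshold:
    @pytest.mark.parametrize("alpha1", [0.08, 0.60, 2.66])
    def test_retained_count_matches_sort_oracle(self, alpha1):
        """Voxels at/above the cutoff match the sort-based top-quantile count."""
        rng = np.random.default_rng(11)
        flat = rng.permutation(1_000_000).astype(float)  # distinct intensities
        vol = _vol(flat.reshape(100, 100, 100))
        cutoff = cumulative_threshold(vol, alpha1)
        # independent oracle: full descending sort
        k = int(np.floor(alpha1 / 100 * flat.size))
        oracle_cutoff = np.sort(flat)[::-1][k - 1]
        assert cutoff == oracle_cutoff
        assert int((flat >= cutoff).sum()) == k

    def test_ties_kept_above(self):
        arr = np.zeros((10, 10, 10))
        arr.ravel()[:30] = 5.0  # 3% of voxels tied at the top
        vol = _vol(arr)
        cutoff = cumulative_threshold(vol, 1.0)  # nominal 10 voxels
        assert cutoff == 5.0
        assert int((arr >= cutoff).sum()) == 30  # ties retained

    def test_constant_volume_warns_and_returns_constant(self):
        vol = _vol(np.full((6, 6, 6), 7.0))
        with pytest.warns(UserWarning, match="constant"):
            assert cumulative_threshold(vol, 0.5) == 7.0

    def test_alpha_out_of_range(self):
        vol = _vol(np.arange(27.0).reshape(3, 3, 3))
        for bad in (0.0, 100.0, -1.0):
            with pytest.raises(ValueError):
                cumulative_threshold(vol, bad)

    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fraction_property(self, seed, alpha1):
        """Retained fraction never exceeds alpha1 percent except through ties."""
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 50, size=(12, 12, 12)).astype(float)
        if arr.max() == arr.min():
            return
        vol = _vol(arr)
        cutoff = cumulative_threshold(vol, alpha1)
        k = max(1, int(np.floor(alpha1 / 100 * arr.size)))
        # strictly above the cutoff: under the quantile; at/above: ties kept
        assert int((arr > cutoff).sum()) < k
        assert int((arr >= cutoff).sum()) >= k


class TestMask:
    def test_cutoff_above_max_empty(self):
        vol = _vol(np.arange(27.0).reshape(3, 3, 3))
        assert not binary_mask(vol, 27.0).any()

    def test_cutoff_at_min_full(self):
        vol = _vol(np.arange(27.0).reshape(3, 3, 3))
        assert binary_mask(vol, 0.0).all()

    def test_single_blob_single_component(self):
        from scipy import ndimage

        vol = make_blob_volume([(0.0, 0.0, 0.0)], 2000.0)
        mask = binary_mask(vol, 500.0)
        _, n = ndimage.label(mask)
        assert n == 1


class TestThinning:
    def test_isolated_voxel_survives(self):
        arr = np.zeros((9, 9, 9))
        arr[4, 4, 4] = 10.0
        vol = _vol(arr)
        cs = extract_candidates(arr > 5.0, vol)
        assert len(cs) == 1
        assert cs.points[0] == pytest.approx(vol.index_to_world(np.array([4, 4, 4])))
        assert cs.intensities[0] == 10.0

    def test_thin_line_preserved_with_endpoints(self):
        arr = np.zeros((30, 9, 9))
        arr[5:25, 4, 4] = 10.0  # 20-voxel straight 1-voxel-thick segment
        vol = _vol(arr)
        cs = extract_candidates(arr > 5.0, vol)
        expected = vol.index_to_world(np.array([[i, 4, 4] for i in range(5, 25)]))
        assert len(cs) == 20
        assert np.allclose(np.sort(cs.points[:, 0]), np.sort(expected[:, 0]))

    def test_solid_cube_matches_reference_skeletonizer(self):
        """A solid 7x7x7 cube thins exactly as the published 3D thinning
        implementation, voxel for voxel."""
        from skimage.morphology import skeletonize as reference_skeletonize

        arr = np.zeros((13, 13, 13))
        arr[3:10, 3:10, 3:10] = 10.0
        vol = _vol(arr)
        mask = arr > 5.0
        cs = extract_candidates(mask, vol)
        ref = np.argwhere(reference_skeletonize(mask))
        got = np.asarray(np.round(vol.world_to_index(cs.points)), dtype=int)
        assert len(cs) == len(ref)
        assert set(map(tuple, got)) == set(map(tuple, ref))

    def test_every_mask_component_contributes_a_candidate(self):
        """Small compact blobs must not vanish under thinning."""
        from scipy import ndimage

        vol = make_blob_volume([(0, 0, 0), (4, 0, 0), (0, 4, 0)], 2000.0)
        mask = binary_mask(vol, 800.0)
        _, n = ndimage.label(mask)
        cs = extract_candidates(mask, vol)
        assert n == 3
        # every component holds at least one candidate
        lab, _ = ndimage.label(mask)
        idx = np.asarray(np.round(vol.world_to_index(cs.points)), dtype=int)
        comps = {lab[tuple(i)] for i in idx}
        assert comps == {1, 2, 3}

    def test_empty_mask_empty_set(self):
        vol = _vol(np.zeros((5, 5, 5)))
        cs = extract_candidates(np.zeros((5, 5, 5), dtype=bool), vol)
        assert len(cs) == 0


class TestSweep:
    def test_clean_phantom_reaches_full_coverage(self, clean_flex24):
        ph = clean_flex24
        roi = extract_roi(ph.volume, ph.gt.positions, 3.0)
        curve, chosen = parametrize_threshold(roi, ph.gt.positions, lo=0.1, hi=2.0, step=0.1)
        assert curve["coverage_pct"].max() == 100.0
        # chosen = smallest alpha1 attaining the maximum
        attaining = curve.loc[curve["coverage_pct"] == 100.0, "alpha1_pct"]
        assert chosen == pytest.approx(attaining.min())

    def test_dim_apical_blobs_uncovered_at_tight_threshold(self):
        """Below the quantile of the dim apical blobs, coverage drops and the
        uncovered electrodes are apical."""
        ph = make_phantom("confusion", "Flex 28", seed=0, noise_sigma=0.0)
        roi = extract_roi(ph.volume, ph.gt.positions, 3.0)
        cs = candidates_from_roi(roi, 0.05)  # far below the apical-blob quantile
        cov = coverage(cs, ph.gt.positions)
        assert cov < 100.0
        from scipy.spatial import cKDTree

        d, _ = cKDTree(cs.points).query(ph.gt.positions)
        uncovered = np.flatnonzero(d > 0.9) + 1  # 1-based electrode labels
        assert uncovered.size > 0
        assert uncovered.min() >= 8  # dim contacts are the 5 most apical

    def test_default_grid_matches_published_sweep(self):
        """Default sweep grid runs 0.01–3.0 % in 0.01 % steps."""
        import inspect

        sig = inspect.signature(parametrize_threshold)
        assert sig.parameters["lo"].default == 0.01
        assert sig.parameters["hi"].default == 3.0
        assert sig.parameters["step"].default == 0.01

    def test_mask_grows_and_coverage_nondecreasing_in_alpha(self, clean_flex24):
        """Larger alpha_1 retains a superset of voxels; on the clean phantom
        the electrode coverage never drops as the threshold loosens.  (The
        skeleton itself is not monotone under thinning, so candidate counts
        may dip even as the mask grows.)"""
        ph = clean_flex24
        roi = extract_roi(ph.volume, ph.gt.positions, 3.0)
        alphas = (0.2, 0.5, 1.0, 2.0)
        mask_sizes, covs = [], []
        for a in alphas:
            cutoff = cumulative_threshold(roi, a)
            mask_sizes.append(int(binary_mask(roi, cutoff).sum()))
            covs.append(coverage(candidates_from_roi(roi, a), ph.gt.positions))
        assert mask_sizes == sorted(mask_sizes)
        assert covs == sorted(covs)

    def test_empty_gt_rejected(self, clean_flex24):
        roi = extract_roi(clean_flex24.volume, clean_flex24.gt.positions, 3.0)
        with pytest.raises(ValueError):
            parametrize_threshold(roi, np.empty((0, 3)))
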