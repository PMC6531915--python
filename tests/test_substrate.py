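"""Synthetic volumes, SD classification, fibrosis, fibers, fixtures."""

import numpy as np
import pytest
from scipy import ndimage

from ivtlab.substrate import (
    LABEL_BZ,
    LABEL_FIBROSIS,
    LABEL_HEALTHY,
    LABEL_SCAR,
    LAYER_ENDO,
    LAYER_EPI,
    LAYER_M,
    RegionMasks,
    SyntheticInfarctSpec,
    TissueGrid,
    VoxelVolume,
    assign_fibers,
    assign_fibrosis,
    assign_transmural_layers,
    generate_synthetic_infarct,
    isthmus_sheet,
    map_voxel_values,
    sd_classify,
    slab,
    strand,
    synthetic_bz_intensity,
)


class TestSyntheticVolume:
    def test_same_seed_bit_identical(self):
        spec = SyntheticInfarctSpec(seed=7)
        v1, m1, t1 = generate_synthetic_infarct(spec)
        v2, m2, t2 = generate_synthetic_infarct(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(t1, t2)

    def test_zero_scar_extent_has_no_scar(self):
        spec = SyntheticInfarctSpec(scar_semiaxes=(0.0, 0.0, 0.0))
        _, _, truth = generate_synthetic_infarct(spec)
        assert not np.any(truth == LABEL_SCAR)

    def test_channel_wider_than_scar_rejected(self):
        with pytest.raises(ValueError, match="wider"):
            generate_synthetic_infarct(
                SyntheticInfarctSpec(scar_semiaxes=(3.0, 3.0, 3.0), channel_width_mm=8.0)
            )

    def test_scar_plateau_floor_enforced(self):
        with pytest.raises(ValueError, match="3 remote SD"):
            SyntheticInfarctSpec(scar_plateau_sd=2.0)

    def test_classifier_recovers_ground_truth_scar(self):
        spec = SyntheticInfarctSpec(seed=3, noise_sd_rel=0.5)
        vol, masks, truth = generate_synthetic_infarct(spec)
        labels = sd_classify(vol, masks, mode="global")
        scar_true = truth == LABEL_SCAR
        recovered = np.mean(labels[scar_true] == LABEL_SCAR)
        assert recovered >= 0.90

    def test_remote_statistics_match_nominal(self):
        spec = SyntheticInfarctSpec(seed=5)
        vol, masks, _ = generate_synthetic_infarct(spec)
        vals = vol.data[masks.remote]
        assert vals.mean() == pytest.approx(spec.mu_r, abs=2.0)
        assert vals.std() == pytest.approx(spec.s_r, rel=0.25)


class TestSdClassify:
    @staticmethod
    def _exact_masks(shape, infarct_slice):
        myo = np.ones(shape, dtype=bool)
        infarct = np.zeros(shape, dtype=bool)
        infarct[infarct_slice] = True
        remote = ~ndimage.binary_dilation(infarct, iterations=2)
        return RegionMasks(myocardium=myo, remote=remote, infarct=infarct)

    def test_uniform_volume_all_healthy(self):
        data = np.full((10, 10, 4), 100.0)
        vol = VoxelVolume(data=data, spacing=1.0)
        masks = self._exact_masks(data.shape, (slice(4, 6), slice(4, 6), slice(1, 3)))
        labels = sd_classify(vol, masks, mode="global")
        assert np.all(labels == LABEL_HEALTHY)

    def test_threshold_application(self):
        # remote voxels alternate 90/110: mean 100, population SD 10
        data = np.full((10, 10, 1), 90.0)
        data[::2] = 110.0
        data[4, 4, 0] = 131.0  # >= mean + 3 SD -> scar
        data[4, 5, 0] = 125.0  # in [mean+2SD, mean+3SD) -> BZ
        data[4, 6, 0] = 115.0  # < mean + 2 SD -> healthy
        infarct = np.zeros(data.shape, dtype=bool)
        infarct[4, 4:7, 0] = True
        remote = np.zeros(data.shape, dtype=bool)
        remote[:2] = True
        vol = VoxelVolume(data=data, spacing=1.0)
        masks = RegionMasks(np.ones_like(infarct), remote, infarct)
        labels = sd_classify(vol, masks, mode="global")
        assert labels[4, 4, 0] == LABEL_SCAR
        assert labels[4, 5, 0] == LABEL_BZ
        assert labels[4, 6, 0] == LABEL_HEALTHY

    def test_counts_match_bruteforce_two_threshold_scan(self):
        vol, masks, _ = generate_synthetic_infarct(SyntheticInfarctSpec(seed=11))
        labels = sd_classify(vol, masks, mode="global")
        mu = vol.data[masks.remote].mean()
        sd = vol.data[masks.remote].std()
        scar = bz = 0
        it = np.nditer(vol.data, flags=["multi_index"])
        for x in it:
            if not masks.infarct[it.multi_index]:
                continue
            if x >= mu + 3 * sd:
                scar += 1
            elif x >= mu + 2 * sd:
                bz += 1
        assert (labels == LABEL_SCAR).sum() == scar
        assert (labels == LABEL_BZ).sum() == bz

    def test_shift_invariance(self):
        vol, masks, _ = generate_synthetic_infarct(SyntheticInfarctSpec(seed=2))
        l1 = sd_classify(vol, masks, mode="per-slice")
        shifted = VoxelVolume(data=vol.data + 37.5, spacing=vol.spacing)
        l2 = sd_classify(shifted, masks, mode="per-slice")
        assert np.array_equal(l1, l2)

    def test_per_slice_missing_remote_names_slice(self):
        data = np.full((6, 6, 3), 100.0)
        infarct = np.zeros(data.shape, dtype=bool)
        infarct[2, 2, 1] = True
        remote = np.zeros(data.shape, dtype=bool)
        remote[0, 0, 0] = True  # no remote voxels on slice 1
        masks = RegionMasks(np.ones_like(infarct), remote, infarct)
        with pytest.raises(ValueError, match="slice 1"):
            sd_classify(VoxelVolume(data=data, spacing=1.0), masks, mode="per-slice")


class TestVoxelToGridMapping:
    def test_aligned_identity_copy(self):
        data = np.arange(4 * 4 * 2, dtype=float).reshape(4, 4, 2)
        vol = VoxelVolume(data=data, spacing=1.0)
        grid = TissueGrid(shape=(4, 4, 2), dx=1.0)
        mapped = map_voxel_values(vol, grid)
        assert np.array_equal(mapped, data)

    def test_64_elements_per_voxel_at_paper_resolutions(self):
        vol = VoxelVolume(data=np.arange(3 * 3 * 3, dtype=float).reshape(3, 3, 3),
                          spacing=1.4)
        # phase the grid so four centroids per axis land in the first voxel
        grid = TissueGrid(shape=(8, 8, 8), dx=0.4, origin=(-0.1, -0.1, -0.1))
        mapped = map_voxel_values(vol, grid)
        _, counts = np.unique(mapped, return_counts=True)
        assert counts.max() == 64

    def test_matches_bruteforce_centroid_assignment(self):
        vol, _, truth = generate_synthetic_infarct(SyntheticInfarctSpec(seed=4))
        grid = TissueGrid(shape=(30, 30, 10), dx=0.7, origin=(10.0, 10.0, 3.0))
        mapped = map_voxel_values(vol, grid, values=truth)
        cent = grid.element_centroids()
        expect = np.empty(cent.shape[0], dtype=truth.dtype)
        for i, c in enumerate(cent):
            idx = tuple(int(np.floor(x / vol.spacing)) for x in c)
            expect[i] = truth[idx]
        assert np.array_equal(mapped.ravel(), expect)

    def test_centroid_outside_volume_rejected(self):
        vol = VoxelVolume(data=np.zeros((4, 4, 4)), spacing=1.0)
        grid = TissueGrid(shape=(10, 2, 2), dx=1.0)
        with pytest.raises(ValueError, match="outside"):
            map_voxel_values(vol, grid)


class TestFibrosis:
    @staticmethod
    def _bz_grid(rng):
        grid = TissueGrid(shape=(10, 10, 2), dx=0.5)
        lab = grid.label.ravel()
        lab[::3] = LABEL_BZ
        grid.label = lab.reshape(grid.shape)
        intens = rng.normal(size=grid.shape)
        return grid, intens

    def test_zero_level_changes_nothing(self, rng):
        grid, intens = self._bz_grid(rng)
        before = grid.label.copy()
        assign_fibrosis(grid, intens, 0.0)
        assert np.array_equal(grid.label, before)

    def test_full_level_converts_all_bz(self, rng):
        grid, intens = self._bz_grid(rng)
        n_bz = (grid.label == LABEL_BZ).sum()
        assign_fibrosis(grid, intens, 100.0)
        assert (grid.label == LABEL_FIBROSIS).sum() == n_bz
        assert (grid.label == LABEL_BZ).sum() == 0

    @pytest.mark.parametrize("level", [10.0, 20.0, 30.0, 33.3])
    def test_exact_count_and_sort_oracle(self, level, rng):
        grid, intens = self._bz_grid(rng)
        bz_idx = np.nonzero(grid.label.ravel() == LABEL_BZ)[0]
        n_expected = int(round(level / 100.0 * bz_idx.size))
        flat = intens.ravel()
        # brute-force full sort: intensity descending, index ascending
        order = sorted(bz_idx, key=lambda i: (-flat[i], i))
        expected = set(order[:n_expected])
        assign_fibrosis(grid, intens, level)
        chosen = set(np.nonzero(grid.label.ravel() == LABEL_FIBROSIS)[0])
        assert chosen == expected
        assert len(chosen) == n_expected

    def test_fibrosis_only_from_bz(self, rng):
        grid, intens = self._bz_grid(rng)
        non_bz_before = grid.label != LABEL_BZ
        assign_fibrosis(grid, intens, 50.0)
        assert not np.any(grid.label[non_bz_before] == LABEL_FIBROSIS)

    def test_out_of_range_level_rejected(self, rng):
        grid, intens = self._bz_grid(rng)
        with pytest.raises(ValueError):
            assign_fibrosis(grid, intens, 101.0)

    def test_patch_size_grows_with_correlation_length(self):
        grid, _ = isthmus_sheet()
        sizes = []
        for corr in (0.5, 2.5):
            g, _ = isthmus_sheet()
            intens = synthetic_bz_intensity(g, seed=9, corr_mm=corr)
            assign_fibrosis(g, intens, 30.0)
            fib = g.label == LABEL_FIBROSIS
            labeled, n = ndimage.label(fib, structure=np.ones((3, 3, 3)))
            sizes.append(fib.sum() / max(n, 1))
        assert sizes[1] > sizes[0]


class TestLayersAndFibers:
    def test_default_cut_points(self):
        grid = TissueGrid(shape=(2, 2, 100), dx=0.1)
        assign_transmural_layers(grid)
        # depths 0.10 / 0.30 / 0.90 fall in endo / M / epi
        assert grid.layer[0, 0, 9] == LAYER_ENDO
        assert grid.layer[0, 0, 29] == LAYER_M
        assert grid.layer[0, 0, 89] == LAYER_EPI

    def test_degenerate_fractions(self):
        grid = TissueGrid(shape=(2, 2, 10), dx=0.4)
        assign_transmural_layers(grid, fractions=(1.0, 0.0, 0.0))
        assert np.all(grid.layer == LAYER_ENDO)

    def test_counts_match_depth_binning_oracle(self):
        grid = TissueGrid(shape=(3, 3, 37), dx=0.3)
        assign_transmural_layers(grid)
        depth = (np.arange(37) + 0.5) / 37
        expect = np.where(depth < 0.17, LAYER_ENDO,
                          np.where(depth < 0.58, LAYER_M, LAYER_EPI))
        for lay in (LAYER_ENDO, LAYER_M, LAYER_EPI):
            assert (grid.layer == lay).sum() == (expect == lay).sum() * 9

    def test_bad_fractions_rejected(self):
        grid = TissueGrid(shape=(2, 2, 10), dx=0.4)
        with pytest.raises(ValueError, match="sum to 1"):
            assign_transmural_layers(grid, fractions=(0.5, 0.2, 0.2))

    def test_mid_depth_fiber_is_circumferential(self):
        grid = TissueGrid(shape=(4, 4, 21), dx=0.2)
        assign_fibers(grid, helix_deg=(60.0, -60.0))
        mid = grid.fiber[0, 0, 10]
        assert mid == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)

    def test_unit_norm_everywhere(self):
        grid = TissueGrid(shape=(5, 5, 12), dx=0.4)
        assign_fibers(grid, helix_deg=(60.0, -60.0), transverse_deg=10.0,
                      smoothing_sigma_mm=0.8)
        norms = np.linalg.norm(grid.fiber, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_zero_smoothing_is_identity(self):
        g1 = TissueGrid(shape=(4, 4, 10), dx=0.4)
        g2 = TissueGrid(shape=(4, 4, 10), dx=0.4)
        assign_fibers(g1, smoothing_sigma_mm=0.0)
        assign_fibers(g2, smoothing_sigma_mm=1e-12)
        assert np.allclose(g1.fiber, g2.fiber, atol=1e-9)


class TestFixtures:
    def test_slab_element_count(self):
        grid = slab(20.0, 20.0, 6.0, dx=0.4)
        assert grid.shape == (50, 50, 15)

    def test_strand_fiber_direction(self):
        grid = strand(fiber_direction=(0.0, 1.0, 0.0))
        assert np.allclose(grid.fiber[..., 1], 1.0)

    def test_indivisible_extent_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            slab(20.1, 20.0, 6.0, dx=0.4)

    def test_zero_width_channel_fully_blocked(self):
        grid, _ = isthmus_sheet(channel_w_lower=0.0, channel_w_upper=0.0)
        # the whole scar band is scar: no BZ corridor crosses it
        x0, x1, y0, y1 = 6.0, 26.0, 6.0, 26.0
        cent = grid.element_centroids().reshape(grid.shape + (3,))
        inside = ((cent[..., 0] >= x0) & (cent[..., 0] <= x1)
                  & (cent[..., 1] >= y0) & (cent[..., 1] <= y1))
        assert np.all(grid.label[inside] == LABEL_SCAR)

    def test_negative_channel_rejected(self):
        with pytest.raises(ValueError):
            isthmus_sheet(channel_w_upper=-1.0)

    def test_label_census_matches_geometry(self):
        grid, lm = isthmus_sheet()
        # channel elements are BZ, scar blocks are scar, remainder labeled
        assert (grid.label == LABEL_SCAR).sum() > 0
        assert (grid.label == LABEL_BZ).sum() > 0
        # every element has exactly one label by construction
        assert set(np.unique(grid.label)) <= {LABEL_HEALTHY, LABEL_SCAR, LABEL_BZ}
        # channel midline is conducting
        i = int(lm["channel_mid"][0] / grid.dx)
        j = int(lm["channel_mid"][1] / grid.dx)
        assert grid.label[i, j, 0] == LABEL_BZ
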