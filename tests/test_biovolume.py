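"""Preprocessing, multilevel Otsu, cube dissection, ratio, thickness."""

import numpy as np
import pytest

from ecmquant.biovolume import (
    CubeStats,
    VolumeGrid,
    denoise,
    dissect_cubes,
    eps_cell_ratio,
    filter_cubes,
    otsu_thresholds,
    segment_channel,
    thickness_map,
    total_class_volume,
    tophat,
)
from ecmquant.synthetic import Scene3DParams, generate_biofilm_stack

from conftest import brute_force_otsu


def grid(arr, pitch=(1.0, 1.0, 1.0), channel=""):
    return VolumeGrid(np.asarray(arr, float), pitch, channel=channel)


class TestDenoise:
    def test_constant_grid_unchanged(self):
        g = grid(np.full((4, 6, 6), 7.0))
        out = denoise(g, kernel=(3, 3, 3))
        assert out.intensities == pytest.approx(g.intensities)

    def test_single_bright_voxel_spreads_over_kernel(self):
        """Kernel (3,3,1): the impulse is averaged over its 9-voxel plane."""
        arr = np.zeros((3, 9, 9))
        arr[1, 4, 4] = 27.0
        out = denoise(grid(arr), kernel=(3, 3, 1))
        # direct summation oracle: mean of the 3x3 in-plane neighborhood
        assert out.intensities[1, 4, 4] == pytest.approx(27.0 / 9)
        assert out.intensities[1, 3, 3] == pytest.approx(27.0 / 9)
        assert out.intensities[1, 2, 4] == pytest.approx(0.0)
        assert out.intensities[0, 4, 4] == pytest.approx(0.0)

    def test_linearity_of_repeated_application(self, rng):
        a = rng.uniform(0, 10, size=(5, 7, 7))
        b = rng.uniform(0, 10, size=(5, 7, 7))
        g = denoise(grid(a + b), (3, 3, 3)).intensities
        s = denoise(grid(a), (3, 3, 3)).intensities + denoise(grid(b), (3, 3, 3)).intensities
        assert g == pytest.approx(s)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            denoise(grid(np.zeros((4, 4, 4))), kernel=(4, 3, 3))


class TestTophat:
    def test_constant_background_zeroed(self):
        out = tophat(grid(np.full((6, 10, 10), 5.0)), 3)
        assert out.intensities == pytest.approx(0.0)

    def test_small_blob_preserved_background_removed(self):
        arr = np.full((8, 12, 12), 10.0)
        arr[3:5, 5:7, 5:7] = 100.0  # 2-voxel blob < element size 5
        out = tophat(grid(arr), 5)
        # morphology oracle: opening of the small blob returns the flat
        # background, so the top-hat keeps the full blob prominence
        assert out.intensities[3, 5, 5] == pytest.approx(90.0)
        assert out.intensities[0, 0, 0] == pytest.approx(0.0)

    def test_output_nonnegative_for_any_input(self, rng):
        arr = rng.uniform(0, 50, size=(6, 8, 8))
        out = tophat(grid(arr), 3)
        assert np.all(out.intensities >= 0)

    def test_oversized_element_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            tophat(grid(np.zeros((4, 10, 10))), 5)


class TestOtsu:
    @pytest.mark.parametrize("n_classes", [2, 3])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_histograms(self, n_classes, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 100, size=64).astype(float)
        counts[rng.integers(0, 64, size=5)] = 0
        if np.count_nonzero(counts) < n_classes:
            counts[:n_classes] = 1
        idx = otsu_thresholds(
            histogram=counts, n_classes=n_classes, return_indices=True
        )
        oracle, _ = brute_force_otsu(counts, n_classes)
        assert tuple(idx) == tuple(oracle)

    def test_two_delta_histogram_threshold_between_modes(self):
        counts = np.zeros(256)
        counts[50] = 40
        counts[200] = 60
        (t,) = otsu_thresholds(histogram=counts, n_classes=2)
        assert 50 < t < 200

    def test_three_separated_modes_assigned_to_classes(self, rng):
        """Each Gaussian mode lands in its own class of the 3-class split."""
        vals = np.concatenate(
            [rng.normal(30, 3, 500), rng.normal(120, 3, 500), rng.normal(220, 3, 500)]
        )
        t1, t2 = otsu_thresholds(vals, n_classes=3)
        assert 30 < t1 < 120 < t2 < 220

    def test_degenerate_constant_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_thresholds(np.full((4, 4, 4), 3.0), n_classes=3)


class TestSegmentChannel:
    def test_floor_of_one_empties_foreground(self, rng):
        g = grid(rng.uniform(1, 100, size=(6, 8, 8)))
        seg = segment_channel(g, floor_threshold=1.0)
        assert not seg.foreground.any()

    def test_noiseless_slab_segmented_exactly(self):
        p = Scene3DParams(
            geometry="slab", slab_thickness=5.0, target_ratio=0.5,
            overlap_fraction=0.0, noise_sd=0.0, seed=7,
        )
        cell, eps, truth = generate_biofilm_stack(p)
        seg = segment_channel(cell, floor_threshold=0.07)
        assert np.array_equal(seg.foreground, truth.cell_mask)

    def test_raising_floor_never_adds_voxels(self, rng):
        g = grid(rng.uniform(0, 255, size=(6, 10, 10)))
        prev = None
        for floor in (0.0, 0.3, 0.6, 0.9):
            fg = segment_channel(g, floor).foreground
            if prev is not None:
                assert not np.any(fg & ~prev)
            prev = fg


def random_segmentation(rng, shape, p):
    from ecmquant.biovolume import ChannelSegmentation

    return ChannelSegmentation(
        foreground=rng.random(shape) < p,
        thresholds=(0.5,),
        floor_threshold=0.0,
        voxel_pitch=(0.5, 0.25, 0.25),
    )


class TestCubes:
    def test_full_cube_biovolume_and_fraction(self):
        shape = (20, 20, 20)
        fg = np.ones(shape, bool)
        from ecmquant.biovolume import ChannelSegmentation

        pitch = (0.5, 0.25, 0.25)
        segs = {
            "cell": ChannelSegmentation(fg, (0.5,), 0.0, pitch),
            "eps": ChannelSegmentation(np.zeros(shape, bool), (0.5,), 0.0, pitch),
        }
        raw = grid(np.ones(shape), pitch)
        cubes = dissect_cubes(segs, raw, cube_side=20)
        assert len(cubes) == 1
        v = 0.5 * 0.25 * 0.25
        assert cubes[0].shape_biovolume == pytest.approx(8000 * v)
        assert cubes[0].rel_cell == 1.0

    def test_cube_sums_conserve_global_voxel_counts(self, rng):
        """Pre-filter cube sums equal whole-stack voxel counts exactly."""
        shape = (13, 27, 31)  # deliberately not divisible by the cube side
        segs = {
            "cell": random_segmentation(rng, shape, 0.3),
            "eps": random_segmentation(rng, shape, 0.2),
        }
        raw = grid(rng.uniform(0, 10, shape), (0.5, 0.25, 0.25))
        v = raw.voxel_volume
        cubes = dissect_cubes(segs, raw, cube_side=5)
        for which, seg in (("cell", segs["cell"]), ("eps", segs["eps"])):
            assert total_class_volume(cubes, which) == seg.foreground.sum() * v
        # the printed formula's float form agrees to round-off
        assert sum(c.shape_biovolume * c.rel_cell for c in cubes) == pytest.approx(
            segs["cell"].foreground.sum() * v
        )

    def test_overlap_bounded_by_class_fractions(self, rng):
        shape = (10, 15, 15)
        segs = {
            "cell": random_segmentation(rng, shape, 0.5),
            "eps": random_segmentation(rng, shape, 0.5),
        }
        cubes = dissect_cubes(segs, grid(np.ones(shape), (0.5, 0.25, 0.25)), 4)
        for c in cubes:
            assert 0 <= c.rel_overlap <= min(c.rel_eps, c.rel_cell) <= 1

    def test_misaligned_shapes_rejected(self, rng):
        segs = {
            "cell": random_segmentation(rng, (10, 10, 10), 0.5),
            "eps": random_segmentation(rng, (10, 10, 12), 0.5),
        }
        with pytest.raises(ValueError, match="misaligned"):
            dissect_cubes(segs, grid(np.ones((10, 10, 10))), 5)


def make_cube(n_eps, n_cell, n_overlap, n_vox=1000, mean=50.0, v=1.0):
    return CubeStats((0, 0, 0), n_vox, n_eps, n_cell, n_overlap, v, mean)


class TestFilterAndRatio:
    def test_zero_floor_is_identity_and_filter_idempotent(self):
        cubes = [make_cube(10, 10, 5, mean=m) for m in (74.0, 75.0, 76.0)]
        assert filter_cubes(cubes, 0.0) == cubes
        once = filter_cubes(cubes, 75.0)
        assert filter_cubes(once, 75.0) == once

    def test_intensity_floor_is_strict(self):
        """Floor 75: of means {74, 75, 76} only the 76 cube survives."""
        cubes = [make_cube(10, 10, 5, mean=m) for m in (74.0, 75.0, 76.0)]
        kept = filter_cubes(cubes, 75.0)
        assert [c.mean_intensity for c in kept] == [76.0]

    def test_ratio_worked_case(self):
        """rel_eps 0.5, rel_overlap 0.1, rel_cell 0.4 -> (0.5-0.1)/0.4 = 1.0"""
        cube = make_cube(n_eps=500, n_cell=400, n_overlap=100)
        res = eps_cell_ratio([cube])
        assert res.ratio == pytest.approx(1.0)

    def test_zero_eps_gives_zero_ratio(self):
        res = eps_cell_ratio([make_cube(0, 400, 0)])
        assert res.ratio == 0.0

    def test_zero_cell_biovolume_raises(self):
        with pytest.raises(ValueError, match="no cell biovolume"):
            eps_cell_ratio([make_cube(10, 0, 0)])


class TestThickness:
    def test_slab_thickness_exact(self):
        """10 occupied z-planes at 0.5 µm pitch -> 5.0 µm everywhere."""
        fg = np.zeros((20, 8, 8), bool)
        fg[:10] = True
        from ecmquant.biovolume import ChannelSegmentation

        seg = ChannelSegmentation(fg, (0.5,), 0.0, (0.5, 0.25, 0.25))
        tm = thickness_map(seg)
        assert tm.local_thickness == pytest.approx(5.0)
        assert tm.mean_thickness == pytest.approx(5.0)
        assert tm.coverage == 1.0

    def test_single_column_top_voxel_index_arithmetic(self):
        fg = np.zeros((10, 4, 4), bool)
        fg[3, 2, 2] = True
        from ecmquant.biovolume import ChannelSegmentation

        seg = ChannelSegmentation(fg, (0.5,), 0.0, (0.5, 1.0, 1.0))
        tm = thickness_map(seg)
        assert tm.local_thickness[2, 2] == pytest.approx(2.0)
        assert tm.coverage == pytest.approx(1 / 16)

    def test_empty_foreground_reports_zero(self):
        from ecmquant.biovolume import ChannelSegmentation

        seg = ChannelSegmentation(np.zeros((5, 4, 4), bool), (), 0.0, (0.5, 1, 1))
        tm = thickness_map(seg)
        assert tm.mean_thickness == 0.0 and tm.coverage == 0.0
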