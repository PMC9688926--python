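"""Morphological gradient, extended minima, watershed, frame segmentation."""

import numpy as np
import pytest

from orgrowth import (
    AcquisitionGeometry,
    SegmentationParams,
    SimulationConfig,
    extended_minima_markers,
    morphological_gradient,
    segment_frame,
    simulate_recording,
    watershed_from_markers,
)
from orgrowth._watershed import flood_watershed
from orgrowth.preprocess import z_project

from _oracles import flood_watershed_oracle


def two_basin_toy():
    """5x5 ridge toy: left basin 0 (cols 0-1), ridge 9 (col 2), right basin 1."""
    img = np.zeros((5, 5))
    img[:, 2] = 9.0
    img[:, 3:] = 1.0
    markers = np.zeros((5, 5), dtype=np.int32)
    markers[2, 0] = 1
    markers[2, 4] = 2
    return img, markers


class TestMorphologicalGradient:
    def test_constant_image_gives_zero(self):
        assert np.array_equal(
            morphological_gradient(np.full((5, 5), 3.0), 2), np.zeros((5, 5))
        )

    def test_step_edge_radius_one(self):
        row = np.array([[0.0, 0.0, 0.0, 9.0, 9.0, 9.0]])
        expected = np.array([[0.0, 0.0, 9.0, 9.0, 0.0, 0.0]])
        assert np.array_equal(morphological_gradient(row, 1), expected)

    def test_invariant_to_additive_constant(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 10, (8, 8))
        assert np.allclose(
            morphological_gradient(img, 2), morphological_gradient(img + 42.0, 2)
        )

    def test_non_negative(self):
        img = np.random.default_rng(1).normal(size=(10, 10))
        assert (morphological_gradient(img, 1) >= 0).all()


class TestExtendedMinima:
    def depth_five_basins(self):
        toy = np.full((5, 5), 20.0)
        toy[1:4, 1] = 5.0
        toy[1:4, 3] = 5.0
        toy[1:4, 2] = 10.0
        return toy

    def test_monotone_ramp_has_single_marker(self):
        ramp = np.arange(48.0).reshape(6, 8)
        assert extended_minima_markers(ramp, 2.0, 4).max() == 1

    @pytest.mark.parametrize("h,expected", [(1.0, 2), (6.0, 1)])
    def test_basin_merging_at_dynamic_h(self, h, expected):
        assert extended_minima_markers(self.depth_five_basins(), h, 4).max() == expected

    def test_h_zero_gives_regional_minima(self):
        from skimage.measure import label as cc_label
        from skimage.morphology import local_minima

        img = np.random.default_rng(2).integers(0, 6, (9, 9)).astype(float)
        got = extended_minima_markers(img, 0.0, 8)
        ref = cc_label(local_minima(img, connectivity=2), connectivity=2)
        assert got.max() == ref.max()
        assert np.array_equal(got > 0, ref > 0)

    def test_marker_count_never_increases_with_h(self):
        img = np.random.default_rng(3).integers(0, 20, (12, 12)).astype(float)
        counts = [extended_minima_markers(img, h, 4).max() for h in (0, 1, 2, 5, 10)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestWatershed:
    def test_two_basin_toy(self):
        img, markers = two_basin_toy()
        lf = watershed_from_markers(img, markers, 4)
        assert (lf.labels == 1).sum() == 10
        assert (lf.labels == 2).sum() == 10
        assert (lf.labels[:, 2] == 0).all()  # ridge column is the line

    def test_single_marker_floods_everything(self):
        img = np.random.default_rng(4).uniform(size=(7, 7))
        markers = np.zeros((7, 7), dtype=np.int32)
        markers[3, 3] = 1
        lf = watershed_from_markers(img, markers, 4)
        assert (lf.labels == 1).all()

    def test_no_markers_rejected(self):
        with pytest.raises(ValueError, match="marker"):
            watershed_from_markers(np.zeros((4, 4)), np.zeros((4, 4), np.int32))

    def test_invariant_to_marker_label_swap(self):
        img, markers = two_basin_toy()
        swapped = np.where(markers == 1, 2, np.where(markers == 2, 1, 0))
        a = watershed_from_markers(img, markers, 4).labels
        b = watershed_from_markers(img, swapped, 4).labels
        assert np.array_equal(a == 1, b == 2)
        assert np.array_equal(a == 2, b == 1)
        assert np.array_equal(a == 0, b == 0)

    def test_labels_partition_the_image(self):
        img = np.random.default_rng(5).integers(0, 9, (11, 11)).astype(float)
        markers = extended_minima_markers(img, 2.0, 4)
        labels = flood_watershed(img, markers, 4)
        region_px = (labels > 0).sum()
        line_px = (labels == 0).sum()
        assert region_px + line_px == img.size

    def test_matches_priority_flood_oracle_on_random_images(self):
        rng = np.random.default_rng(6)
        for conn in (4, 8):
            for _ in range(8):
                h, w = rng.integers(4, 12, 2)
                img = rng.integers(0, 7, (h, w)).astype(float)
                markers = extended_minima_markers(img, 1.0, conn)
                if markers.max() < 1:
                    continue
                assert np.array_equal(
                    flood_watershed(img, markers, conn),
                    flood_watershed_oracle(img, markers, conn),
                )

    def test_region_interiors_agree_with_skimage_watershed(self):
        """Independent cross-check on the classic two-touching-disks
        landscape: away from the (convention-dependent) boundary pixels,
        flooded basins match skimage's watershed."""
        from scipy import ndimage
        from skimage.segmentation import watershed as sk_watershed

        mask = np.zeros((50, 80), dtype=bool)
        yy, xx = np.mgrid[:50, :80]
        mask |= (yy - 25) ** 2 + (xx - 28) ** 2 <= 20**2
        mask |= (yy - 25) ** 2 + (xx - 52) ** 2 <= 20**2
        img = -ndimage.distance_transform_edt(mask)
        markers = np.zeros_like(img, dtype=np.int32)
        markers[25, 28] = 1
        markers[25, 52] = 2
        ours = flood_watershed(img, markers, 8)
        theirs = sk_watershed(img, markers, connectivity=2, mask=mask)
        for lab in (1, 2):
            interior = ndimage.binary_erosion(ours == lab, iterations=2) & mask
            assert interior.any()
            assert (theirs[interior] == lab).all()


class TestSegmentFrame:
    def make_frame(self, n=3, radius=90.0, noise=0.0, seed=5):
        g = AcquisitionGeometry(
            tile_rows=1, tile_cols=1, z_planes=1, n_frames=1, tile_shape_px=(768, 768)
        )
        cfg = SimulationConfig(
            geometry=g,
            n_organoids=n,
            initial_radius_um=(radius, 0.03),
            noise_sd=noise,
            illumination_gradient_amplitude=0.0,
            seed=seed,
        )
        stacks, gt = simulate_recording(cfg)
        return z_project(stacks["untreated"][0, :, 0]), gt, g

    def test_recovers_isolated_organoids_and_areas(self):
        frame, gt, g = self.make_frame()
        lf = segment_frame(frame, SegmentationParams(), g.pixel_size_um)
        assert lf.n_objects == 3
        from orgrowth import measure_regions

        m = measure_regions(lf, g.pixel_size_um).sort_values("cx_um")
        t = gt.sort_values("cx_um")
        for measured, true in zip(m.area_um2, t.true_lumen_area_um2):
            assert measured == pytest.approx(true, rel=0.05)

    def test_blank_frame_yields_empty_labeling(self):
        blank = np.full((128, 128), 1000.0)
        lf = segment_frame(blank, SegmentationParams(), 1.29)
        assert lf.n_objects == 0
        assert not lf.labels.any()

    def test_min_area_above_largest_organoid_removes_everything(self):
        frame, _, g = self.make_frame()
        params = SegmentationParams(min_area_um2=1e9)
        assert segment_frame(frame, params, g.pixel_size_um).n_objects == 0

    def test_increasing_min_area_never_increases_object_count(self):
        frame, _, g = self.make_frame(noise=300.0)
        counts = [
            segment_frame(
                frame, SegmentationParams(min_area_um2=a), g.pixel_size_um
            ).n_objects
            for a in (100.0, 500.0, 5000.0, 40000.0)
        ]
        assert all(x >= y for x, y in zip(counts, counts[1:]))

    def test_labels_are_consecutive_and_ordered_by_area(self):
        frame, _, g = self.make_frame(noise=200.0)
        lf = segment_frame(frame, SegmentationParams(), g.pixel_size_um)
        ids, counts = np.unique(lf.labels[lf.labels > 0], return_counts=True)
        assert list(ids) == list(range(1, lf.n_objects + 1))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
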