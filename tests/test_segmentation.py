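"""Tests for stain separation, binarization and region delineation."""
import numpy as np
import pytest
from scipy import ndimage

import lymphquant as lq
from lymphquant.errors import NoTissueError, ShapeError
from lymphquant.types import SectionImage

from tests.helpers import brute_force_otsu, dice, random_section_spec


def _image_of(pixel_rgb, shape=(4, 4)):
    px = np.empty(shape + (3,), np.uint8)
    px[:, :] = pixel_rgb
    return SectionImage(px, 0.005)


class TestExcessChannel:
    def test_saturated_blue(self):
        assert lq.excess_channel(_image_of((0, 0, 255)), "blue")[0, 0] == 255

    @pytest.mark.parametrize("v", [0, 17, 128, 255])
    def test_achromatic_cancellation(self, v):
        img = _image_of((v, v, v))
        assert (lq.excess_channel(img, "blue") == 0).all()
        assert (lq.excess_channel(img, "red") == 0).all()

    def test_direct_formula(self):
        assert lq.excess_channel(_image_of((100, 50, 200)), "blue")[0, 0] == 250
        assert lq.excess_channel(_image_of((150, 40, 30)), "red")[0, 0] == 230


class TestBinarize:
    def test_fixed_threshold_definition(self):
        grey = np.array([[100, 200], [200, 100]], np.uint8)
        mask = lq.binarize(grey, "fixed", 128)
        assert np.array_equal(mask, grey == 200)

    def test_otsu_bimodal_covers_bright_class(self):
        grey = np.concatenate([np.full(600, 10), np.full(400, 200)])
        grey = grey.reshape(40, 25).astype(np.uint8)
        mask = lq.binarize(grey, "otsu")
        assert np.array_equal(mask, grey == 200)

    def test_constant_grid_warns_and_returns_empty(self):
        grey = np.zeros((8, 8), np.uint8)
        with pytest.warns(UserWarning):
            mask = lq.binarize(grey, "otsu")
        assert not mask.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_on_binary_images(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((32, 32)) > 0.5
        grey = mask.astype(np.uint8) * 255
        assert np.array_equal(lq.binarize(grey, "fixed", 128), mask)

    @pytest.mark.parametrize("seed", range(10))
    def test_otsu_matches_exhaustive_search(self, seed):
        """Implementation threshold equals the brute-force 256-way maximum
        between-class-variance search on arbitrary 8-bit data."""
        rng = np.random.default_rng(seed)
        # mixtures of 2-3 noisy modes, the regime Otsu is meant for
        parts = [rng.normal(rng.uniform(0, 255), rng.uniform(2, 40),
                            rng.integers(50, 400))
                 for _ in range(rng.integers(2, 4))]
        grey = np.clip(np.concatenate(parts), 0, 255).astype(np.uint8)
        assert lq.otsu_threshold(grey) == brute_force_otsu(grey)

    def test_otsu_agrees_with_skimage_on_clean_bimodal(self):
        from skimage.filters import threshold_otsu

        grey = np.concatenate([np.full(500, 30), np.full(500, 220)])
        grey = grey.astype(np.uint8)
        ours = lq.otsu_threshold(grey)
        theirs = threshold_otsu(grey)
        assert np.array_equal(grey > ours, grey > theirs)


class TestCleanMask:
    def test_noop(self):
        rng = np.random.default_rng(0)
        mask = rng.random((20, 20)) > 0.7
        assert np.array_equal(lq.clean_mask(mask, 0, fill_holes=False), mask)

    def test_small_components_removed(self):
        mask = np.zeros((30, 30), bool)
        mask[1:2, 1:4] = True          # 3 px
        mask[10:15, 10:20] = True      # 50 px
        out = lq.clean_mask(mask, min_object_px=10)
        assert out.sum() == 50
        assert out[12, 15] and not out[1, 2]

    def test_empty_in_empty_out(self):
        mask = np.zeros((10, 10), bool)
        assert not lq.clean_mask(mask, 5, fill_holes=True).any()

    def test_hole_filling(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        mask[9:11, 9:11] = False
        out = lq.clean_mask(mask, 0, fill_holes=True)
        assert out[9, 9] and out.sum() == 100


class TestTissueRegion:
    def test_blank_slide_raises(self):
        with pytest.raises(NoTissueError):
            lq.tissue_region(_image_of((245, 245, 245), (64, 64)))

    def test_synthetic_ellipse_recovered_exactly(self):
        spec = random_section_spec(seed=2, noise_sd=0.0)
        image, truth = lq.generate_section(spec)
        assert dice(lq.tissue_region(image), truth.tissue_mask) == 1.0

    def test_fully_tinted_canvas_gives_full_mask(self):
        assert lq.tissue_region(_image_of((100, 100, 100), (64, 64))).all()


class TestTumorRegion:
    def test_empty_in_empty_out(self):
        assert not lq.tumor_region(np.zeros((40, 40), bool)).any()

    def test_scattered_small_components_vanish(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((80, 80), bool)
        for _ in range(10):
            r, c = rng.integers(5, 70, 2)
            mask[r:r + 2, c:c + 2] = True
        assert not lq.tumor_region(mask, closing_radius_px=0,
                                   min_area_px=500).any()

    def test_matches_reference_morphology(self):
        """Closing + fill equals an independently composed
        dilation-then-erosion-then-fill with the same disc."""
        rng = np.random.default_rng(3)
        mask = np.zeros((90, 90), bool)
        rr, cc = np.ogrid[:90, :90]
        disc = (rr - 45) ** 2 + (cc - 45) ** 2 <= 25 ** 2
        mask[disc] = rng.random((90, 90))[disc] > 0.35  # porous tumor mass
        ours = lq.tumor_region(mask, closing_radius_px=5, min_area_px=100)

        r = 5
        yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
        footprint = yy ** 2 + xx ** 2 <= r ** 2
        ref = ndimage.binary_dilation(mask, footprint)
        ref = ndimage.binary_erosion(ref, footprint, border_value=1)
        ref = ndimage.binary_fill_holes(ref)
        labels, n = ndimage.label(ref, structure=np.ones((3, 3)))
        counts = np.bincount(labels.ravel())
        for i in range(1, n + 1):
            if counts[i] < 100:
                ref[labels == i] = False
        assert np.array_equal(ours, ref)


class TestPartition:
    def test_empty_tumor_all_peritumoral(self):
        tissue = np.zeros((20, 20), bool)
        tissue[2:18, 2:18] = True
        p = lq.partition_regions(tissue, np.zeros_like(tissue))
        assert np.array_equal(p.peritumoral, tissue)

    def test_tumor_covers_tissue(self):
        tissue = np.ones((10, 10), bool)
        p = lq.partition_regions(tissue, tissue)
        assert not p.peritumoral.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_pixel_count_conservation(self, seed):
        rng = np.random.default_rng(seed)
        tissue = rng.random((40, 40)) > 0.4
        tumor = rng.random((40, 40)) > 0.6  # arbitrary, even outside tissue
        p = lq.partition_regions(tissue, tumor)
        assert p.tumor.sum() + p.peritumoral.sum() == p.tissue.sum()
        assert not (p.tumor & p.peritumoral).any()
        assert not (p.tumor & ~p.tissue).any()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            lq.partition_regions(np.ones((5, 5), bool), np.ones((6, 6), bool))


class TestSegmentSection:
    @pytest.mark.parametrize("seed", range(4))
    def test_noise_free_recovery_is_exact(self, seed):
        spec = random_section_spec(seed=40 + seed, n_vessels=8,
                                   with_tumor=True, noise_sd=0.0)
        image, truth = lq.generate_section(spec)
        seg = lq.segment_section(image)
        assert dice(seg.vessel_mask, truth.vessel_mask) == 1.0
        assert dice(seg.tumor_cell_mask, truth.tumor_mask) == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_noisy_recovery_stays_accurate(self, seed):
        spec = random_section_spec(seed=60 + seed, n_vessels=8,
                                   with_tumor=True, noise_sd=5.0)
        image, truth = lq.generate_section(spec)
        seg = lq.segment_section(image)
        assert dice(seg.vessel_mask, truth.vessel_mask) >= 0.95
        assert dice(seg.tumor_cell_mask, truth.tumor_mask) >= 0.95

    def test_control_section_has_no_tumor(self):
        spec = random_section_spec(seed=77, n_vessels=6, with_tumor=False,
                                   noise_sd=5.0)
        image, _ = lq.generate_section(spec)
        seg = lq.segment_section(image)
        assert not seg.tumor_cell_mask.any()
        assert not seg.partition.tumor.any()
        assert np.array_equal(seg.partition.peritumoral, seg.partition.tissue)

    def test_manual_threshold_override_honored(self):
        spec = random_section_spec(seed=78, n_vessels=5, noise_sd=0.0)
        image, truth = lq.generate_section(spec)
        seg = lq.segment_section(
            image, lq.SegmentationParams(vessel_threshold=200.0))
        assert seg.vessel_threshold == 200.0
        assert dice(seg.vessel_mask, truth.vessel_mask) == 1.0
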