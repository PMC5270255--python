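"""Tests for border-distance maps, Parzen densities and Lmax."""
import math

import numpy as np
import pytest
from scipy import ndimage

import lymphquant as lq
from lymphquant.errors import InsufficientDataError, NoTissueError

from tests.helpers import (brute_force_border_distance, random_blob_mask,
                           random_section_spec)


class TestBorderDistanceMap:
    def test_border_pixels_are_zero(self):
        tissue = np.zeros((9, 9), bool)
        tissue[2:7, 2:7] = True
        dmap = lq.border_distance_map(tissue, 1.0)
        assert dmap[2, 4] == 0.0 and dmap[6, 2] == 0.0

    def test_square_center_distance(self):
        tissue = np.zeros((9, 9), bool)
        tissue[2:7, 2:7] = True  # solid 5x5
        dmap = lq.border_distance_map(tissue, 1.0)
        assert dmap[4, 4] == pytest.approx(2.0)

    def test_nan_outside_tissue(self):
        tissue = np.zeros((9, 9), bool)
        tissue[2:7, 2:7] = True
        dmap = lq.border_distance_map(tissue, 1.0)
        assert np.isnan(dmap[0, 0])

    def test_grid_edge_tissue_counts_as_border(self):
        tissue = np.ones((7, 7), bool)
        dmap = lq.border_distance_map(tissue, 1.0)
        assert dmap[0, 3] == 0.0
        assert dmap[3, 3] == pytest.approx(3.0)

    def test_disc_matches_brute_force(self):
        rr, cc = np.ogrid[:31, :31]
        tissue = (rr - 15) ** 2 + (cc - 15) ** 2 <= 13 ** 2
        ours = lq.border_distance_map(tissue, 0.01)
        ref = brute_force_border_distance(tissue, 0.01)
        assert np.allclose(np.nan_to_num(ours), np.nan_to_num(ref), atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_blobs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        tissue = random_blob_mask(rng, (40, 40))
        ours = lq.border_distance_map(tissue, 0.005)
        ref = brute_force_border_distance(tissue, 0.005)
        assert np.allclose(np.nan_to_num(ours), np.nan_to_num(ref), atol=1e-9)

    def test_empty_tissue_raises(self):
        with pytest.raises(NoTissueError):
            lq.border_distance_map(np.zeros((5, 5), bool), 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_dilated_tissue_never_decreases_distances(self, seed):
        rng = np.random.default_rng(100 + seed)
        tissue = random_blob_mask(rng, (40, 40))
        bigger = ndimage.binary_dilation(tissue)
        d1 = lq.border_distance_map(tissue, 1.0)
        d2 = lq.border_distance_map(bigger, 1.0)
        sel = tissue
        assert np.all(d2[sel] >= d1[sel] - 1e-9)


class TestVesselDistances:
    def _setup(self):
        tissue = np.zeros((15, 15), bool)
        tissue[1:14, 1:14] = True
        dmap = lq.border_distance_map(tissue, 0.1)
        return tissue, dmap

    def test_empty_vessel_mask(self):
        _, dmap = self._setup()
        assert lq.vessel_distances(np.zeros((15, 15), bool), dmap).size == 0

    def test_pixels_mode_reads_each_pixel(self):
        _, dmap = self._setup()
        vessel = np.zeros((15, 15), bool)
        vessel[2, 2] = vessel[3, 5] = vessel[7, 7] = True
        vals = lq.vessel_distances(vessel, dmap, "pixels")
        expected = sorted([dmap[2, 2], dmap[3, 5], dmap[7, 7]])
        assert sorted(vals) == pytest.approx(expected)

    def test_sections_mode_single_value_per_component(self):
        _, dmap = self._setup()
        vessel = np.zeros((15, 15), bool)
        vessel[6, 5:8] = True  # one 3-px component, centroid at (6, 6)
        vals = lq.vessel_distances(vessel, dmap, "sections")
        assert vals.shape == (1,)
        assert vals[0] == pytest.approx(dmap[6, 6])

    def test_pixels_outside_tissue_dropped_with_warning(self):
        tissue, dmap = self._setup()
        vessel = np.zeros((15, 15), bool)
        vessel[0, 0] = vessel[5, 5] = True  # (0, 0) is off-tissue
        with pytest.warns(UserWarning):
            vals = lq.vessel_distances(vessel, dmap, "pixels")
        assert vals.shape == (1,)


class TestParzenDensity:
    @pytest.mark.parametrize("n", [1, 2, 10, 1000])
    def test_unit_area(self, n):
        rng = np.random.default_rng(n)
        d = rng.uniform(0, 1, n)
        sd = lq.parzen_density(d)
        assert abs(sd.auc - 1.0) <= 1e-3

    def test_unit_area_for_identical_distances(self):
        sd = lq.parzen_density([0.3] * 25)
        assert abs(sd.auc - 1.0) <= 1e-3

    def test_single_observation_closed_form(self):
        d0, h = 0.25, 0.05
        grid = np.linspace(0.0, 0.5, 501)  # contains d0 exactly
        sd = lq.parzen_density([d0], bandwidth_mm=h, grid=grid)
        expected = (1.0 / (h * math.sqrt(2 * math.pi))) * (
            1.0 + math.exp(-2.0 * d0 ** 2 / h ** 2))
        assert lq.density_at(sd, d0) == pytest.approx(expected, rel=1e-6)

    def test_density_nonnegative(self):
        rng = np.random.default_rng(5)
        sd = lq.parzen_density(rng.exponential(0.2, 200))
        assert (sd.density >= 0).all()

    def test_lmax_within_support(self):
        sd = lq.parzen_density([0.1, 0.7, 0.3])
        assert sd.lmax_mm == 0.7
        assert sd.lmax_mm <= sd.support.max()

    def test_zero_variance_uses_bandwidth_floor(self):
        sd = lq.parzen_density([0.5, 0.5, 0.5])
        assert sd.bandwidth_mm > 0

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            lq.parzen_density([])


class TestDensityAt:
    def test_grid_point_exact(self):
        sd = lq.parzen_density([0.1, 0.2, 0.4], bandwidth_mm=0.05)
        i = 100
        assert lq.density_at(sd, float(sd.support[i])) == sd.density[i]

    def test_midpoint_is_mean_of_neighbors(self):
        sd = lq.parzen_density([0.1, 0.2, 0.4], bandwidth_mm=0.05)
        mid = 0.5 * (sd.support[10] + sd.support[11])
        assert lq.density_at(sd, float(mid)) == pytest.approx(
            0.5 * (sd.density[10] + sd.density[11]))

    def test_beyond_support_is_zero(self):
        sd = lq.parzen_density([0.1, 0.2])
        assert lq.density_at(sd, float(sd.support.max()) + 1.0) == 0.0


class TestLmax:
    def test_maximum(self):
        assert lq.lmax([0.1, 0.7, 0.3]) == 0.7

    def test_single(self):
        assert lq.lmax([0.42]) == 0.42

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            lq.lmax([])

    def test_deep_vessel_geometry(self):
        """A vessel placed 1.2 mm deep in a round tissue reports Lmax 1.2 mm
        to within one pixel."""
        px = 0.005
        depth_px = 240  # 1.2 mm
        canvas = (560, 560)
        tissue = lq.Ellipse((280, 280), (250, 250))
        vessel = lq.VesselSpec((280, 280), 10, 10, filled=True)
        spec = lq.SyntheticSpec(seed=0, canvas=canvas, pixel_size_mm=px,
                                tissue_geometry=tissue, vessels=(vessel,))
        _, truth = lq.generate_section(spec)
        dmap = lq.border_distance_map(truth.tissue_mask, px)
        d = lq.vessel_distances(truth.vessel_mask, dmap, "pixels")
        assert lq.lmax(d) == pytest.approx(depth_px * px + 10 * px, abs=px)


def test_density_mode_recovers_vessel_depth():
    """Vessels concentrated in a thin annulus at depth d* put the density
    mode within one bandwidth of d*."""
    px = 0.005
    tissue = lq.Ellipse((200, 200), (170, 170))
    depth_px = 60  # d* = 0.3 mm
    ring_r = 170 - depth_px
    vessels = tuple(
        lq.VesselSpec((200 + ring_r * math.sin(t), 200 + ring_r * math.cos(t)),
                      5, 2)
        for t in np.linspace(0, 2 * math.pi, 14, endpoint=False)
    )
    spec = lq.SyntheticSpec(seed=0, canvas=(400, 400), pixel_size_mm=px,
                            tissue_geometry=tissue, vessels=vessels)
    _, truth = lq.generate_section(spec)
    dmap = lq.border_distance_map(truth.tissue_mask, px)
    d = lq.vessel_distances(truth.vessel_mask, dmap, "pixels")
    sd = lq.parzen_density(d)
    mode = sd.support[np.argmax(sd.density)]
    assert abs(mode - depth_px * px) <= sd.bandwidth_mm + 5 * px
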