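"""Preprocessing, segmentation, centres of mass and region masking."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from conftest import make_image
from punctaprox.detect import (RegionMask, apply_region_mask,
                               ball_structuring_element, centre_of_mass,
                               gaussian_blur, segment_particles,
                               subtract_background)
from punctaprox.synthgen import RenderSpec, render_image


def disk_image(centres_px, radius_px, shape=(64, 64), value=100.0, pixel_size=0.02):
    """Raster of hard disks at given (row, col) centres."""
    raster = np.zeros(shape)
    rr, cc = np.indices(shape)
    for r0, c0 in centres_px:
        raster[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px ** 2] = value
    return make_image(raster, pixel_size=pixel_size)


class TestGaussianBlur:
    def test_sigma_scaled_to_pixels(self):
        """A 0.015 µm sigma on a 0.02 µm/px image is a 0.75 px kernel."""
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(0)
        img = make_image(rng.uniform(0, 10, (32, 32)), pixel_size=0.02)
        out = gaussian_blur(img, 0.015)
        np.testing.assert_allclose(out.raster,
                                   gaussian_filter(img.raster, 0.75))

    def test_constant_image_unchanged(self):
        img = make_image(np.full((16, 16), 7.0))
        np.testing.assert_allclose(gaussian_blur(img, 0.03).raster, 7.0)

    def test_zero_sigma_is_identity(self):
        rng = np.random.default_rng(1)
        img = make_image(rng.uniform(0, 5, (8, 8)))
        np.testing.assert_array_equal(gaussian_blur(img, 0.0).raster, img.raster)

    def test_impulse_matches_direct_convolution(self):
        """Blur of an impulse equals brute-force discrete Gaussian convolution."""
        img = make_image(np.zeros((41, 41)), pixel_size=0.02)
        img.raster[20, 20] = 1.0
        sigma_px = 0.03 / 0.02
        radius = int(4 * sigma_px + 0.5)
        ax = np.arange(-radius, radius + 1)
        k1 = np.exp(-ax ** 2 / (2 * sigma_px ** 2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        oracle = convolve2d(img.raster, kernel, mode="same")
        np.testing.assert_allclose(gaussian_blur(img, 0.03).raster, oracle,
                                   atol=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(make_image(np.zeros((4, 4))), -0.01)


class TestBackgroundSubtraction:
    def test_flat_image_goes_to_zero(self):
        img = make_image(np.full((16, 16), 40.0))
        assert np.all(subtract_background(img, 3).raster == 0.0)

    def test_matches_bruteforce_opening(self):
        """Pixel-for-pixel agreement with an explicit erosion/dilation oracle
        using the same non-flat ball structuring element (9×9 image, r=2)."""
        rng = np.random.default_rng(2)
        raster = rng.uniform(0, 100, (9, 9))
        img = make_image(raster)
        footprint, height = ball_structuring_element(2)
        r = 2
        padded = np.pad(raster, r, mode="reflect")
        eroded = np.zeros_like(raster)
        for i in range(9):
            for j in range(9):
                window = padded[i:i + 2 * r + 1, j:j + 2 * r + 1]
                eroded[i, j] = np.min(window[footprint] - height[footprint])
        padded_e = np.pad(eroded, r, mode="reflect")
        opened = np.zeros_like(raster)
        for i in range(9):
            for j in range(9):
                window = padded_e[i:i + 2 * r + 1, j:j + 2 * r + 1]
                opened[i, j] = np.max(window[footprint] + height[footprint])
        expected = np.clip(raster - opened, 0.0, None)
        np.testing.assert_allclose(subtract_background(img, 2).raster, expected)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(3)
        img = make_image(rng.uniform(0, 50, (20, 20)))
        assert np.all(subtract_background(img, 3).raster >= 0)

    def test_invalid_radius_rejected(self):
        img = make_image(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            subtract_background(img, 0)
        with pytest.raises(ValueError):
            subtract_background(img, 10)


class TestCentreOfMass:
    def test_weighted_mean_closed_form(self):
        """Intensities 1 and 3 at x-indices 0 and 1 put the CoM at index 0.75."""
        img = make_image(np.array([[1.0, 3.0]]), pixel_size=0.1)
        mask = np.ones((1, 2), dtype=bool)
        x, y = centre_of_mass(img, mask)
        assert x == pytest.approx((0.75 + 0.5) * 0.1)
        assert y == pytest.approx(0.5 * 0.1)

    def test_uniform_disk_gives_geometric_centre(self):
        img = disk_image([(32, 32)], 10)
        mask = img.raster > 0
        x, y = centre_of_mass(img, mask)
        assert x == pytest.approx((32 + 0.5) * 0.02, abs=1e-9)
        assert y == pytest.approx((32 + 0.5) * 0.02, abs=1e-9)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(4)
        raster = rng.uniform(0, 10, (15, 15))
        mask = rng.random((15, 15)) > 0.5
        img = make_image(raster, pixel_size=0.05)
        x, y = centre_of_mass(img, mask)
        w = raster[mask]
        rr, cc = np.nonzero(mask)
        assert x == pytest.approx(np.sum((cc + 0.5) * w) / w.sum() * 0.05)
        assert y == pytest.approx(np.sum((rr + 0.5) * w) / w.sum() * 0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            centre_of_mass(make_image(np.ones((4, 4))), np.zeros((4, 4), bool))


class TestSegmentation:
    def test_blank_image_gives_empty_set(self):
        img = make_image(np.zeros((32, 32)))
        assert len(segment_particles(img, img)) == 0

    def test_disk_fixture_with_area_cap(self):
        """Five disks, one exceeding the 0.02 µm² cap: four survive, and
        centroids agree with construction within 0.5 px."""
        centres = [(10, 10), (10, 40), (40, 10), (40, 40), (25, 25)]
        img = disk_image(centres[:4], 2, shape=(64, 64))
        big = disk_image([centres[4]], 6, shape=(64, 64))
        img.raster += big.raster  # radius-6 disk: 113 px > 50 px cap
        found = segment_particles(img, img, threshold=50.0)
        assert len(found) == 4
        coords = found.coords()
        for r0, c0 in centres[:4]:
            expect = np.array([(c0 + 0.5) * 0.02, (r0 + 0.5) * 0.02])
            err_px = np.min(np.linalg.norm(coords - expect, axis=1)) / 0.02
            assert err_px < 0.5

    def test_filter_monotonicity(self):
        """Widening the area or circularity window never removes a particle."""
        rng = np.random.default_rng(5)
        centres = [(int(r), int(c)) for r, c in rng.uniform(5, 59, (6, 2))]
        img = disk_image(centres, 2, shape=(64, 64))
        narrow = segment_particles(img, img, min_area_um2=0.001,
                                   max_area_um2=0.01, circ_min=0.5, circ_max=1.0,
                                   threshold=50.0)
        wide = segment_particles(img, img, min_area_um2=0.0, max_area_um2=0.05,
                                 circ_min=0.0, circ_max=1.0, threshold=50.0)
        narrow_coords = {tuple(np.round(c, 9)) for c in narrow.coords()}
        wide_coords = {tuple(np.round(c, 9)) for c in wide.coords()}
        assert narrow_coords <= wide_coords

    def test_translation_equivariance(self):
        """Whole-pixel shifts of a noise-free image shift centroids identically."""
        img = disk_image([(20, 20), (20, 45)], 2, shape=(70, 70))
        shifted = make_image(np.roll(img.raster, (7, 11), axis=(0, 1)),
                             pixel_size=0.02)
        p0 = segment_particles(img, img, threshold=50.0).coords()
        p1 = segment_particles(shifted, shifted, threshold=50.0).coords()
        delta = np.array([11 * 0.02, 7 * 0.02])  # (x, y) shift
        np.testing.assert_allclose(np.sort(p1, axis=0),
                                   np.sort(p0 + delta, axis=0), atol=1e-9)

    def test_detects_rendered_puncta(self):
        """On a clean rendered field of well-separated puncta, detected count
        equals generated count and the centroid RMS error is sub-pixel."""
        rng = np.random.default_rng(6)
        pts = rng.uniform(1.0, 9.0, (25, 2))
        spec = RenderSpec(photons_per_punctum=2000.0, background_rate=0.5, seed=7)
        img = render_image(pts, spec, field_size=(10.0, 10.0))
        from punctaprox.pipeline import DetectionConfig, detect_channel
        found = detect_channel(img, DetectionConfig())
        assert len(found) == 25
        coords = found.coords()
        errs = [np.min(np.linalg.norm(coords - p, axis=1)) for p in pts]
        assert np.sqrt(np.mean(np.square(errs))) < img.pixel_size

    def test_shape_mismatch_rejected(self):
        a = make_image(np.zeros((8, 8)))
        b = make_image(np.zeros((9, 9)))
        with pytest.raises(ValueError):
            segment_particles(a, b)

    def test_circularity_clipped_to_one(self):
        img = disk_image([(10, 10)], 1, shape=(20, 20))
        found = segment_particles(img, img, threshold=50.0)
        assert len(found) == 1
        assert 0.0 <= found.particles[0].circularity <= 1.0


class TestRegionMask:
    def _particles(self, coords):
        from punctaprox.detect import Particle, ParticleSet
        parts = [Particle(x, y, 0.001, 1.0, 1.0, 1.0, 1) for x, y in coords]
        return ParticleSet(parts, 0.02)

    def test_whole_field_mask_is_identity(self):
        rng = np.random.default_rng(7)
        pset = self._particles(rng.uniform(0, 10, (30, 2)))
        mask = RegionMask(polygon=[[-1, -1], [11, -1], [11, 11], [-1, 11]])
        assert len(apply_region_mask(pset, mask)) == 30

    def test_edge_particle_counted_inside(self):
        pset = self._particles([(0.0, 0.5)])  # exactly on the left edge
        mask = RegionMask(polygon=[[0, 0], [1, 0], [1, 1], [0, 1]])
        assert len(apply_region_mask(pset, mask)) == 1

    def test_polygon_matches_raster_oracle(self):
        """Polygon membership agrees with a fine rasterised-mask oracle for
        points away from the boundary."""
        from shapely.geometry import Point, Polygon
        poly = np.array([[1.0, 1.0], [8.0, 2.0], [6.0, 8.0], [2.0, 6.0]])
        mask = RegionMask(polygon=poly)
        shapely_poly = Polygon(poly)
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 10, (400, 2))
        ps = 0.01
        raster = mask.as_raster((1000, 1000), ps)
        clear = np.array([shapely_poly.exterior.distance(Point(p)) > 2 * ps
                          for p in pts])
        member_poly = mask.contains(pts)
        rows = np.clip((pts[:, 1] / ps).astype(int), 0, 999)
        cols = np.clip((pts[:, 0] / ps).astype(int), 0, 999)
        member_raster = raster[rows, cols]
        np.testing.assert_array_equal(member_poly[clear], member_raster[clear])

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError):
            RegionMask(polygon=[[0, 0], [1, 1], [1, 0], [0, 1]])
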