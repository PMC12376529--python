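"""Wrinkling percentage, FRET ratio, ring masks and morphometry."""

import numpy as np
import pytest
from scipy import ndimage

from nucleomech import nucleus_quant as nq
from nucleomech import synthetic_data as sd
from nucleomech.errors import QualityError, SegmentationError


def _disk_mask(shape, radius, center=None):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = center or (shape[0] / 2, shape[1] / 2)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def brute_force_wrinkling(pixels, mask):
    """Independent per-pixel double loop implementing the definition."""
    total = 0
    vals = []
    for i in range(pixels.shape[0]):
        for j in range(pixels.shape[1]):
            if mask[i, j]:
                vals.append(pixels[i, j])
                total += 1
    mean = sum(vals) / total
    bright = sum(1 for v in vals if v > mean)
    return 100.0 * bright / total


class TestSegmentation:
    def test_disk_recovered(self):
        img = np.zeros((64, 64))
        disk = _disk_mask(img.shape, 15)
        img[disk] = 100.0
        mask = nq.segment_nucleus(img)
        assert (mask.mask == disk).all()

    def test_constant_image_rejected(self):
        with pytest.raises(SegmentationError):
            nq.segment_nucleus(np.full((32, 32), 7.0))

    def test_generator_nucleus_jaccard(self):
        img, truth_mask, _ = sd.gen_wrinkled_nucleus_image(seed=3, wrinkle_fraction=0.3,
                                                           noise_sd=0.02)
        seg = nq.segment_nucleus(img)
        inter = (seg.mask & truth_mask.mask).sum()
        union = (seg.mask | truth_mask.mask).sum()
        assert inter / union >= 0.95


class TestWrinkling:
    def test_uniform_nucleus_is_zero(self):
        img = np.zeros((64, 64))
        mask = _disk_mask(img.shape, 20)
        img[mask] = 50.0
        assert nq.ne_wrinkling_percent(img, mask) == 0.0

    def test_half_bright_is_fifty(self):
        img = np.zeros((20, 10))
        mask = np.zeros_like(img, dtype=bool)
        mask[:10] = True   # 100 pixels
        img[:5] = 2.0      # 50 bright at 2, 50 at 0; mean 1
        assert nq.ne_wrinkling_percent(img, mask) == 50.0

    def test_matches_brute_force_on_generator(self):
        img, mask, frac = sd.gen_wrinkled_nucleus_image(seed=9, wrinkle_fraction=0.3)
        fast = nq.ne_wrinkling_percent(img, mask)
        slow = brute_force_wrinkling(img.pixels, mask.mask)
        assert fast == slow
        assert fast == pytest.approx(100 * frac, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 1000, (24, 24)).astype(float)
        mask = _disk_mask(img.shape, 9)
        assert nq.ne_wrinkling_percent(img, mask) == brute_force_wrinkling(img, mask)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(4)
        img = rng.random((32, 32)) * 300
        mask = _disk_mask(img.shape, 12)
        base = nq.ne_wrinkling_percent(img, mask)
        assert nq.ne_wrinkling_percent(2.5 * img + 40.0, mask) == base

    def test_range(self):
        rng = np.random.default_rng(1)
        for s in range(10):
            img = rng.random((16, 16)) * 100
            mask = _disk_mask(img.shape, 6)
            v = nq.ne_wrinkling_percent(img, mask)
            assert 0.0 <= v < 100.0


class TestRingMask:
    def test_annulus_width_by_distance_transform(self):
        mask = _disk_mask((64, 64), 20)
        ring = nq.make_ring_mask(mask, thickness=3)
        dist = ndimage.distance_transform_edt(mask)
        # ring pixels hug the boundary; interior pixels deeper than the
        # thickness stay excluded
        assert ring.mask[dist > 4.5].sum() == 0
        assert (dist[ring.mask] <= 4.5).all()
        assert ring.mask.sum() > 0

    def test_ring_subset_of_nucleus(self):
        mask = _disk_mask((48, 48), 14)
        ring = nq.make_ring_mask(mask, thickness=2)
        assert not (ring.mask & ~mask).any()

    def test_overthick_ring_rejected(self):
        mask = _disk_mask((48, 48), 10)
        with pytest.raises(ValueError):
            nq.make_ring_mask(mask, thickness=12)


class TestFret:
    def test_proportional_channels(self):
        donor = np.full((32, 32), 50.0)
        acceptor = 2.0 * donor
        ring = nq.make_ring_mask(_disk_mask((32, 32), 10), 2).mask
        ratio, mean = nq.fret_ratio_map(acceptor, donor, ring, 0.0, 0.0)
        assert mean == pytest.approx(2.0)
        np.testing.assert_allclose(ratio[ring], 2.0)

    def test_worked_background_subtraction(self):
        """(200 - 100) / (150 - 100) = 2.0."""
        donor = np.full((16, 16), 150.0)
        acceptor = np.full((16, 16), 200.0)
        ring = _disk_mask((16, 16), 5)
        _, mean = nq.fret_ratio_map(acceptor, donor, ring, 100.0, 100.0)
        assert mean == pytest.approx(2.0)

    def test_generator_recovery_with_noise(self):
        img_a, img_d, ring, truth = sd.gen_fret_pair(seed=2, true_ratio=1.5, noise_frac=0.02)
        _, mean = nq.fret_ratio_map(img_a, img_d, ring, 100.0, 100.0)
        assert mean == pytest.approx(truth, rel=0.01)

    def test_common_scaling_invariance(self):
        img_a, img_d, ring, _ = sd.gen_fret_pair(seed=5, true_ratio=1.2)
        _, m1 = nq.fret_ratio_map(img_a, img_d, ring, 100.0, 100.0)
        s = 3.7
        _, m2 = nq.fret_ratio_map(s * img_a.pixels, s * img_d.pixels, ring,
                                  s * 100.0, s * 100.0)
        assert m2 == pytest.approx(m1, rel=1e-12)

    def test_weak_donor_rejected(self):
        donor = np.full((32, 32), 99.0)  # below background everywhere
        acceptor = np.full((32, 32), 200.0)
        ring = _disk_mask((32, 32), 8)
        with pytest.raises(QualityError):
            nq.fret_ratio_map(acceptor, donor, ring, 100.0, 100.0)


class TestMorphometry:
    def test_disk_circularity_and_aspect(self):
        mask = _disk_mask((256, 256), 80)
        area, circ, aspect = nq.nuclear_morphometry(mask)
        assert area == mask.sum()
        assert circ == pytest.approx(1.0, abs=0.05)
        assert aspect == pytest.approx(1.0, abs=0.02)

    def test_square_circularity(self):
        mask = np.zeros((128, 128), dtype=bool)
        mask[20:100, 20:100] = True
        _, circ, _ = nq.nuclear_morphometry(mask)
        assert circ == pytest.approx(np.pi / 4.0, rel=0.05)

    def test_ellipse_aspect_ratio(self):
        yy, xx = np.mgrid[0:256, 0:256]
        mask = ((yy - 128) / 50.0) ** 2 + ((xx - 128) / 100.0) ** 2 <= 1.0
        _, _, aspect = nq.nuclear_morphometry(mask)
        assert aspect == pytest.approx(2.0, abs=0.05)

    def test_rotation_90_exact(self):
        yy, xx = np.mgrid[0:200, 0:200]
        mask = ((yy - 100) / 40.0) ** 2 + ((xx - 100) / 80.0) ** 2 <= 1.0
        a1 = nq.nuclear_morphometry(mask)
        a2 = nq.nuclear_morphometry(np.rot90(mask).copy())
        assert a1[0] == a2[0]
        assert a1[1] == pytest.approx(a2[1], rel=1e-9)
        assert a1[2] == pytest.approx(a2[2], rel=1e-9)

    def test_multi_component_rejected(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:15, 5:15] = True
        mask[40:50, 40:50] = True
        with pytest.raises(ValueError):
            nq.nuclear_morphometry(mask)

    def test_pixel_size_scales_area(self):
        mask = _disk_mask((64, 64), 10)
        a1, _, _ = nq.nuclear_morphometry(mask)
        a2, _, _ = nq.nuclear_morphometry(mask, pixel_size=0.5)
        assert a2 == pytest.approx(a1 * 0.25)
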