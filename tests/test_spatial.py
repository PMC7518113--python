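"""Spatial features: first-order statistics, GLCM construction and its four
statistics, and the binary-texture dispersion features."""

import math

import numpy as np
import pytest

from gbradiomics import (
    BinaryMask,
    GrayscaleImage,
    SPATIAL_FEATURE_NAMES,
    binary_texture_features,
    first_order_features,
    glcm,
    glcm_statistics,
    spatial_features,
)
from gbradiomics.masks import binarize_lesion, extract_reference_region
from conftest import constant_image, disk_mask


def _masks_for(image_shape, lesion_box):
    lesion = np.zeros(image_shape, bool)
    r0, r1, c0, c1 = lesion_box
    lesion[r0:r1, c0:c1] = True
    lesion = BinaryMask(lesion)
    return lesion, extract_reference_region(lesion, margin_px=2)


class TestFirstOrder:
    def test_constant_lesion_over_constant_reference(self):
        img = np.full((20, 20), 50, np.uint8)
        img[8:12, 8:12] = 100
        image = GrayscaleImage(img, 0.01)
        lesion, ref = _masks_for((20, 20), (8, 12, 8, 12))
        f = first_order_features(image, lesion, ref)
        assert f["IMean"] == 100 and f["SD"] == 0 and f["CoV"] == 0
        assert f["HistEntropy"] == 0
        assert f["RImean"] == pytest.approx(2.0)
        assert f["RImedian"] == pytest.approx(2.0)

    def test_two_value_lesion_histogram_entropy_one_bit(self):
        img = np.full((20, 20), 10, np.uint8)
        img[8:12, 8:10] = 0
        img[8:12, 10:12] = 255
        image = GrayscaleImage(img, 0.01)
        lesion, ref = _masks_for((20, 20), (8, 12, 8, 12))
        f = first_order_features(image, lesion, ref)
        assert f["IMedian"] == pytest.approx(127.5)
        assert f["HistEntropy"] == pytest.approx(1.0)

    def test_gaussian_lesion_moments_match_sampling(self):
        rng = np.random.default_rng(1)
        vals = np.clip(rng.normal(128, 20, 10_000), 0, 255)
        img = np.zeros((110, 110), np.uint8)
        img[5:105, 5:105] = vals.reshape(100, 100).astype(np.uint8)
        image = GrayscaleImage(img, 0.01)
        lesion, ref = _masks_for((110, 110), (5, 105, 5, 105))
        f = first_order_features(image, lesion, ref)
        assert abs(f["Skewness"]) < 0.08
        assert f["Kurtosis"] == pytest.approx(3.0, abs=0.15)  # non-excess convention

    def test_zero_reference_ratio_is_missing(self):
        img = np.zeros((20, 20), np.uint8)
        img[8:12, 8:12] = 100
        image = GrayscaleImage(img, 0.01)
        lesion, ref = _masks_for((20, 20), (8, 12, 8, 12))
        f = first_order_features(image, lesion, ref)
        assert math.isnan(f["RImean"]) and math.isnan(f["RImedian"])


def _checkerboard(n, block=1):
    yy, xx = np.mgrid[0:n, 0:n]
    return (((yy // block) + (xx // block)) % 2 * 255).astype(np.uint8)


class TestGLCM:
    def test_constant_lesion_single_diagonal_entry(self):
        image = constant_image((10, 10), 100)
        lesion = BinaryMask(np.ones((10, 10), bool))
        P = glcm(image, lesion, d=1)
        assert P.sum() == pytest.approx(1.0)
        nz = np.nonzero(P)
        assert len(nz[0]) == 1 and nz[0][0] == nz[1][0]
        assert glcm_statistics(P) == pytest.approx((1.0, 0.0, 0.0, 1.0))

    def test_checkerboard_horizontal_pairs_enumerated_by_hand(self):
        image = GrayscaleImage(_checkerboard(4), 0.01)
        lesion = BinaryMask(np.ones((4, 4), bool))
        P = glcm(image, lesion, d=1, levels=2, angles=(0.0,))
        # every horizontal neighbour pair alternates levels: P(0,1)=P(1,0)=1/2
        assert P[0, 1] == pytest.approx(0.5) and P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == 0 and P[1, 1] == 0
        ener, cont, entr, homo = glcm_statistics(P)
        assert (ener, cont, entr, homo) == pytest.approx((0.5, 1.0, 1.0, 0.5))

    def test_matrix_symmetric_and_normalized_on_random_lesion(self):
        rng = np.random.default_rng(2)
        image = GrayscaleImage(rng.integers(0, 256, (30, 30)).astype(np.uint8), 0.01)
        lesion = BinaryMask(disk_mask(10, 30).pixels)
        for d in (1, 5, 14):
            P = glcm(image, lesion, d)
            assert P.sum() == pytest.approx(1.0)
            assert np.allclose(P, P.T)
            ener, cont, entr, homo = glcm_statistics(P)
            assert 0 < ener <= 1 and 0 < homo <= 1 and cont >= 0 and entr >= 0

    def test_pairs_crossing_lesion_boundary_are_excluded(self):
        # lesion = left half dark, right half bright, but masked to left half:
        # no bright level should appear in the matrix at all
        img = np.zeros((8, 8), np.uint8)
        img[:, 4:] = 255
        image = GrayscaleImage(img, 0.01)
        lesion = np.zeros((8, 8), bool)
        lesion[:, :4] = True
        P = glcm(image, BinaryMask(lesion), d=1, levels=2)
        assert P[0, 0] == pytest.approx(1.0)

    def test_tiny_lesion_with_no_pair_reports_none(self):
        image = constant_image((20, 20))
        lesion = np.zeros((20, 20), bool)
        lesion[5, 5] = True
        assert glcm(image, BinaryMask(lesion), d=3) is None

    def test_contrast_shift_invariance_and_mean_shift(self):
        rng = np.random.default_rng(3)
        base = rng.integers(30, 180, (20, 20)).astype(np.uint8)
        lesion = BinaryMask(np.ones((20, 20), bool))
        shifted = GrayscaleImage((base + 40).astype(np.uint8), 0.01)
        # a +40 shift moves every pixel exactly 10 bins at 64 levels,
        # leaving all level differences (hence Cont) unchanged
        c0 = glcm_statistics(glcm(GrayscaleImage(base, 0.01), lesion, 1))[1]
        c1 = glcm_statistics(glcm(shifted, lesion, 1))[1]
        assert c0 == pytest.approx(c1)
        assert shifted.pixels.mean() - base.mean() == pytest.approx(40)

    def test_coarser_checkerboard_lowers_contrast(self):
        lesion = BinaryMask(np.ones((32, 32), bool))
        conts = []
        for block in (1, 2, 4, 8):
            image = GrayscaleImage(_checkerboard(32, block), 0.01)
            conts.append(glcm_statistics(glcm(image, lesion, 1, levels=2))[1])
        assert all(a > b for a, b in zip(conts, conts[1:]))


class TestBinaryTexture:
    def test_full_disk_dispersion_approaches_two_thirds(self):
        # mean distance to the centre of a uniform disk is 2R/3
        for radius, tol in ((20, 0.03), (60, 0.01)):
            disk = disk_mask(radius)
            ar, cdd, dd = binary_texture_features(disk, disk)
            assert ar == 1.0
            assert cdd == pytest.approx(2.0 / 3.0, abs=tol)
            assert dd == pytest.approx(2.0 / 3.0, abs=tol)

    def test_single_center_pixel_has_zero_dispersion(self):
        disk = disk_mask(10)
        high = np.zeros(disk.shape, bool)
        cy, cx = np.argwhere(disk.pixels).mean(axis=0).round().astype(int)
        high[cy, cx] = True
        ar, cdd, dd = binary_texture_features(disk, BinaryMask(high))
        assert dd == pytest.approx(0.0, abs=0.05)
        assert cdd == pytest.approx(0.0, abs=0.05)

    def test_two_symmetric_blobs_match_brute_force(self):
        lesion = disk_mask(15, 41)
        high = np.zeros(lesion.shape, bool)
        high[18:23, 10:15] = True
        high[18:23, 26:31] = True
        high &= lesion.pixels
        ar, cdd, dd = binary_texture_features(lesion, BinaryMask(high))
        # brute force over pixel coordinates
        ly, lx = np.nonzero(lesion.pixels)
        hy, hx = np.nonzero(high)
        r_eq = math.sqrt(len(lx) / math.pi)
        lc = (lx.mean(), ly.mean())
        hc = (hx.mean(), hy.mean())
        cdd_bf = np.mean([math.hypot(x - lc[0], y - lc[1]) for x, y in zip(hx, hy)]) / r_eq
        dd_bf = np.mean([math.hypot(x - hc[0], y - hc[1]) for x, y in zip(hx, hy)]) / r_eq
        assert cdd == pytest.approx(cdd_bf) and cdd > 0
        assert dd == pytest.approx(dd_bf)

    def test_subset_violation_rejected(self):
        lesion = disk_mask(5)
        high = np.ones(lesion.shape, bool)
        with pytest.raises(ValueError):
            binary_texture_features(lesion, BinaryMask(high))


class TestSpatialSet:
    def test_72_names_emitted_in_stable_order(self, small_cohort):
        les = small_cohort[0]
        from gbradiomics.masks import rasterize_contour

        lesion = rasterize_contour(les.contour, les.image.shape)
        high = binarize_lesion(les.image, lesion)
        ref = extract_reference_region(lesion)
        feats = spatial_features(les.image, lesion, high, ref)
        assert tuple(feats.keys()) == SPATIAL_FEATURE_NAMES
        assert len(feats) == 72
        glcm_names = [n for n in feats if n[:4] in ("Ener", "Cont", "Entr", "Homo")]
        assert len(glcm_names) == 60
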