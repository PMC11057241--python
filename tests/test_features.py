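"""Feature-family contracts: hand examples, invariances, cross-checks."""

import json
from pathlib import Path

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.feature import graycomatrix, graycoprops

from cyclescope import features as ft
from cyclescope import synthetic_data as sd
from cyclescope.segmentation import NucleusROI, segment_field

GOLDEN_PATH = Path(__file__).parent / "data" / "golden_features.json"


def make_roi(mask: np.ndarray, origin=(0, 0)) -> NucleusROI:
    rows, cols = np.nonzero(mask)
    r0, c0 = origin
    return NucleusROI(1, (r0, c0, r0 + mask.shape[0], c0 + mask.shape[1]),
                      mask, (r0 + rows.mean(), c0 + cols.mean()),
                      int(mask.sum()))


def disc_mask(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return yy * yy + xx * xx <= radius * radius


class TestCatalog:
    def test_240_unique_names_with_family_counts(self):
        catalog = ft.default_catalog()
        names = [f.name for f in catalog]
        assert len(names) == 240
        assert len(set(names)) == 240
        counts = {}
        for f in catalog:
            counts[f.family] = counts.get(f.family, 0) + 1
        assert counts == {"intensity": 9, "basic_morphology": 4, "SER": 16,
                          "haralick": 4, "STAR": 207}

    def test_star_variant_names_match_field_convention(self):
        names = ft.catalog_names()
        assert "Nucleus Radial Mean" in names
        assert "Nucleus Radial Mean SER-Edge" in names
        assert "Nucleus Symmetry 03 SER-Dark" in names


class TestIntensityProperties:
    def test_constant_pixels(self):
        roi = make_roi(np.ones((2, 2), bool))
        vals = ft.intensity_properties(roi, np.full((2, 2), 10.0))
        mean, sd, median, vmax, vmin, total, cv, q50, contrast = vals
        assert (mean, sd, cv, contrast, total) == (10, 0, 0, 0, 40)

    def test_hand_computed_values(self):
        roi = make_roi(np.ones((2, 2), bool))
        img = np.array([[2.0, 4.0], [6.0, 8.0]])
        mean, sd, median, vmax, vmin, total, cv, q50, contrast = \
            ft.intensity_properties(roi, img)
        assert (total, mean, median, vmax, vmin) == (20, 5, 5, 8, 2)
        assert contrast == pytest.approx(0.6)
        assert q50 == median

    @pytest.mark.parametrize("k", [0.5, 3.0, 117.0])
    def test_homogeneity_under_intensity_scaling(self, k):
        rng = np.random.default_rng(1)
        img = rng.uniform(10, 200, (6, 6))
        roi = make_roi(np.ones((6, 6), bool))
        base = ft.intensity_properties(roi, img)
        scaled = ft.intensity_properties(roi, k * img)
        # mean, sd, median, max, min, sum scale by k
        assert scaled[:6] == pytest.approx(k * base[:6])
        # CV, quantile ratio... CV and contrast are scale-free
        assert scaled[6] == pytest.approx(base[6])
        assert scaled[8] == pytest.approx(base[8])

    def test_empty_mask_rejected(self):
        roi = NucleusROI(1, (0, 0, 2, 2), np.zeros((2, 2), bool), (0, 0), 0)
        with pytest.raises(ValueError):
            ft.intensity_properties(roi, np.ones((2, 2)))


class TestBasicMorphology:
    def test_disc_roundness_and_isotropy(self):
        roi = make_roi(disc_mask(20))
        area, roundness, width, length = ft.basic_morphology(roi)
        assert roundness >= 0.95
        assert length / width <= 1.05

    def test_rectangle_axis_ratio(self):
        # second-moment ellipse of a 10x40 rectangle: 4:1 axes
        roi = make_roi(np.ones((10, 40), bool))
        _, _, width, length = ft.basic_morphology(roi)
        assert length / width == pytest.approx(4.0, rel=0.05)

    def test_area_in_physical_units(self):
        mask = np.zeros((10, 10), bool)
        mask[:10, :10] = True
        roi = make_roi(mask)
        area = ft.basic_morphology(roi, pixel_size_um=1.0)[0]
        assert area == 100.0
        assert ft.basic_morphology(roi, pixel_size_um=0.5)[0] == 25.0

    def test_single_pixel_degenerate_convention(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        area, roundness, width, length = ft.basic_morphology(
            make_roi(mask), pixel_size_um=2.0)
        assert (roundness, width, length) == (1.0, 2.0, 2.0)


class TestSERFilterBank:
    def test_constant_image_all_zero(self):
        bank = ft.ser_filter_bank(np.full((32, 32), 55.0), sigma=1.0)
        for name, resp in bank.items():
            assert np.abs(resp).max() == 0.0, name

    def test_gaussian_blob_is_a_spot(self):
        # closed form: at the center of an isotropic bright Gaussian the
        # Hessian eigenvalues are equal and negative
        yy, xx = np.mgrid[-24:25, -24:25].astype(float)
        img = 1000.0 * np.exp(-(yy ** 2 + xx ** 2) / (2 * 16.0))
        bank = ft.ser_filter_bank(img, sigma=2.0)
        c = (24, 24)
        assert bank["spot"][c] > bank["ridge"][c]
        assert bank["spot"][c] > bank["valley"][c]
        assert bank["spot"][c] > bank["saddle"][c]
        assert bank["spot"][c] > bank["hole"][c]

    def test_bright_line_is_a_ridge(self):
        img = np.zeros((49, 49))
        img[:, 24] = 1000.0
        img = ndi.gaussian_filter(img, 1.5)
        bank = ft.ser_filter_bank(img, sigma=2.0)
        crest = (24, 24)
        assert bank["ridge"][crest] > bank["spot"][crest]

    def test_responses_non_negative(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 500, (40, 40))
        for resp in ft.ser_filter_bank(img, sigma=1.0).values():
            assert resp.min() >= 0.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ft.ser_filter_bank(np.zeros((8, 8)), sigma=0.0)


class TestHaralick:
    def test_constant_roi_degenerate(self):
        roi = make_roi(np.ones((4, 4), bool))
        out = ft.haralick_features(roi, np.full((4, 4), 9.0))
        assert out.tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_checkerboard_mass_on_extremes(self):
        # hand-built GLCM: all axial pairs are (0,31)/(31,0)
        roi = make_roi(np.ones((2, 2), bool))
        img = np.array([[0.0, 31.0], [31.0, 0.0]])
        contrast, correlation, homogeneity, sum_var = \
            ft.haralick_features(roi, img)
        assert homogeneity == pytest.approx(1.0 / (1.0 + 31 ** 2))
        assert contrast == pytest.approx(31.0 ** 2)
        assert correlation == pytest.approx(-1.0)

    def test_glcm_normalized(self):
        rng = np.random.default_rng(3)
        mask = disc_mask(8)
        quant = rng.integers(0, 32, mask.shape)
        glcm = ft._masked_glcm(quant, mask)
        assert glcm.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_skimage_on_rectangular_roi(self):
        # independent oracle: on a full rectangle the masked GLCM equals
        # skimage's (symmetric, axial offsets)
        rng = np.random.default_rng(4)
        img = rng.integers(0, 32, (12, 15))
        roi = make_roi(np.ones(img.shape, bool))
        ours = ft.haralick_features(roi, img.astype(float) * (31 / 31))
        ref = graycomatrix(img.astype(np.uint8), [1], [0, np.pi / 2],
                           levels=32, symmetric=True)
        ref = ref[:, :, 0, :].sum(axis=2).astype(float)
        ref /= ref.sum()
        idx = np.arange(32.0)
        contrast = (ref * (idx[:, None] - idx[None, :]) ** 2).sum()
        assert ours[0] == pytest.approx(contrast, rel=1e-12)
        homog = (ref / (1 + (idx[:, None] - idx[None, :]) ** 2)).sum()
        assert ours[2] == pytest.approx(homog, rel=1e-12)


class TestStarProperties:
    def test_all_intensity_at_centroid(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        mask[2, 3] = True
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        out = ft.star_properties(make_roi(mask), img)
        assert out[17] == 0.0  # radial mean

    def test_uniform_ring_radial_mean(self):
        r = 8
        yy, xx = np.mgrid[-10:11, -10:11]
        dist = np.hypot(yy, xx)
        mask = np.abs(dist - r) < 0.5
        out = ft.star_properties(make_roi(mask), mask.astype(float))
        assert out[17] == pytest.approx(r, abs=0.5)

    def test_two_pixel_hand_example(self):
        # intensities 3 and 1 at distances 1 and 3 from the weighted
        # centroid: radial mean (3*1 + 1*3)/4 = 1.5
        mask = np.zeros((1, 5), bool)
        mask[0, 0] = mask[0, 4] = True
        img = np.zeros((1, 5))
        img[0, 0], img[0, 4] = 3.0, 1.0
        out = ft.star_properties(make_roi(mask), img)
        assert out[17] == pytest.approx(1.5)

    def test_symmetric_blob_low_asymmetry(self):
        # flat-top blob with a smooth taper: little mass sits at tiny
        # radii, where angular quantization would otherwise leave an
        # irreducible 8-fold lattice harmonic
        yy, xx = np.mgrid[-17:18, -17:18].astype(float)
        r = np.hypot(yy, xx)
        img = np.where(r <= 12, 1.0,
                       np.where(r <= 16,
                                np.cos((r - 12) / 4 * np.pi / 2) ** 2, 0.0))
        out = ft.star_properties(make_roi(img > 0), img)
        assert out[:8].max() <= 0.05

    def test_profile_correlation_sign(self):
        # intensity increasing toward the interior correlates positively
        # with border distance
        mask = disc_mask(10)
        interior = ndi.distance_transform_edt(mask)
        out = ft.star_properties(make_roi(mask), interior + 1.0)
        assert out[21] > 0.9

    def test_compactness_of_convex_set_is_one(self):
        out = ft.star_properties(make_roi(disc_mask(9)),
                                 disc_mask(9).astype(float))
        assert out[8:13] == pytest.approx(np.ones(5), abs=0.02)


class TestExtractFeatures:
    def test_vector_length_and_finiteness(self, default_field):
        fld, rois, corrected = default_field
        ex = ft.FieldFeatureExtractor(corrected, fld.pixel_size_um)
        vec = ex.features(rois[0])
        assert vec.shape == (240,)
        assert np.isfinite(vec).all()

    def test_translation_invariance(self, noiseless_field):
        fld, rois, corrected = noiseless_field
        roi = min(rois, key=lambda r: abs(r.centroid[0] - 256)
                  + abs(r.centroid[1] - 256))
        base = ft.FieldFeatureExtractor(corrected, 1.0).features(roi)
        dr, dc = 9, 13
        shifted_img = np.roll(corrected, (dr, dc), axis=(0, 1))
        r0, c0, r1, c1 = roi.bbox
        shifted_roi = NucleusROI(roi.label,
                                 (r0 + dr, c0 + dc, r1 + dr, c1 + dc),
                                 roi.mask, (roi.centroid[0] + dr,
                                            roi.centroid[1] + dc),
                                 roi.area_px)
        shifted = ft.FieldFeatureExtractor(shifted_img, 1.0).features(
            shifted_roi)
        np.testing.assert_allclose(shifted, base, rtol=1e-6, atol=1e-9)

    def test_rotation_by_90_degrees(self, noiseless_field):
        fld, rois, corrected = noiseless_field
        roi = rois[len(rois) // 2]
        base = ft.FieldFeatureExtractor(corrected, 1.0).features(roi)
        rot = np.rot90(corrected)
        h = corrected.shape[1]
        r0, c0, r1, c1 = roi.bbox
        rot_roi = NucleusROI(roi.label, (h - c1, r0, h - c0, r1),
                             np.rot90(roi.mask),
                             (h - 1 - roi.centroid[1], roi.centroid[0]),
                             roi.area_px)
        rotated = ft.FieldFeatureExtractor(rot, 1.0).features(rot_roi)
        np.testing.assert_allclose(rotated, base, rtol=0.02, atol=1e-6)

    def test_intensity_doubling_homogeneity(self, noiseless_field):
        fld, rois, corrected = noiseless_field
        roi = rois[0]
        names = ft.catalog_names()
        base = ft.FieldFeatureExtractor(corrected, 1.0).features(roi)
        doubled = ft.FieldFeatureExtractor(2.0 * corrected, 1.0).features(roi)
        for i, name in enumerate(names):
            if name in ("Intensity Nucleus Mean", "Intensity Nucleus Sum",
                        "Intensity Nucleus Max", "Intensity Nucleus Median"):
                assert doubled[i] == pytest.approx(2 * base[i], rel=1e-6)
            if name in ("Intensity Nucleus CV %", "Intensity Nucleus "
                        "Contrast", "Nucleus Radial Mean",
                        "Nucleus Symmetry 01", "Nucleus Area"):
                assert doubled[i] == pytest.approx(base[i], rel=1e-6,
                                                   abs=1e-9)

    def test_golden_fixture_frozen_values(self):
        """The catalog order and values are frozen by a golden vector."""
        fld = sd.render_field([sd.CellState("SG2M", 3.0)],
                              noise=sd.NoiseParams.none(), seed=99)
        rois, corrected = segment_field(fld)
        assert len(rois) == 1
        vec = ft.FieldFeatureExtractor(corrected,
                                       fld.pixel_size_um).features(rois[0])
        golden = json.loads(GOLDEN_PATH.read_text())
        assert golden["names"] == ft.catalog_names()
        np.testing.assert_allclose(vec, np.array(golden["values"]),
                                   rtol=1e-6, atol=1e-9)
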