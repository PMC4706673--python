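"""HSB compartment segmentation, tissue fractions, peri-ductal band."""

import numpy as np
import pytest
from skimage.color import hsv2rgb

from collagenkit.histoseg import (
    Compartment,
    SegConfig,
    SegmentationMask,
    periductal_band,
    segment_tissue,
    stain_positive_fraction,
    tissue_fractions,
)
from collagenkit.synthetic import gen_histology


def _uniform_rgb(hsv_triplet, shape=(32, 32)):
    hsv = np.broadcast_to(np.array(hsv_triplet), shape + (3,))
    return (hsv2rgb(hsv) * 255).astype(np.uint8)


EXPLICIT = SegConfig(brightness_cuts=(0.45, 0.75), hue_cuts=(0.25, 0.6))


def test_uniform_bright_high_hue_is_adipose():
    image = _uniform_rgb((0.8, 0.4, 0.85))
    mask = segment_tissue(image, EXPLICIT)
    assert (mask.labels == Compartment.ADIPOSE).all()


def test_dark_low_hue_blob_on_midtone_field_is_epithelial():
    image = _uniform_rgb((0.45, 0.5, 0.6), (64, 64)).copy()
    blob = _uniform_rgb((0.08, 0.6, 0.3), (16, 16))
    image[24:40, 24:40] = blob
    mask = segment_tissue(image, EXPLICIT)
    assert (mask.labels[28:36, 28:36] == Compartment.EPITHELIAL).all()
    assert (mask.labels[:8, :8] == Compartment.STROMAL).all()


def test_generated_image_agreement_with_truth_exceeds_90_percent():
    image, truth, _ = gen_histology(
        {"epithelial": 0.05, "adipose": 0.45, "stromal": 0.40}, seed=7
    )
    mask = segment_tissue(image)  # auto thresholds
    agreement = (mask.labels == truth.labels).mean()
    assert agreement >= 0.90


def test_segmentation_idempotent_and_translation_equivariant():
    image, _, _ = gen_histology(
        {"epithelial": 0.1, "adipose": 0.4, "stromal": 0.4}, image_size=128,
        seed=3,
    )
    mask1 = segment_tissue(image)
    mask2 = segment_tissue(image)
    np.testing.assert_array_equal(mask1.labels, mask2.labels)
    rolled = np.roll(image, (13, -7), axis=(0, 1))
    mask_rolled = segment_tissue(rolled)
    np.testing.assert_array_equal(
        mask_rolled.labels, np.roll(mask1.labels, (13, -7), axis=(0, 1))
    )


def test_empty_tissue_image_flagged():
    image = _uniform_rgb((0.0, 0.0, 0.98))  # bare slide
    mask = segment_tissue(image)
    assert mask.is_empty
    assert tissue_fractions(mask).empty


# ---------------------------------------------------------------------------
# fractions


def test_fractions_count_tissue_pixels_only():
    labels = np.zeros((20, 20), dtype=np.uint8)
    labels[:10, :10] = Compartment.ADIPOSE  # 100 px
    labels[10:, :10] = Compartment.STROMAL  # 100 px
    fr = tissue_fractions(SegmentationMask(labels=labels, pixel_size=1.0))
    assert fr.adipose == pytest.approx(0.5)
    assert fr.stromal == pytest.approx(0.5)
    assert fr.epithelial == 0.0
    assert fr.tissue_area == pytest.approx(200.0)


def test_fractions_recovered_from_generator_truth():
    req = {"epithelial": 0.05, "adipose": 0.45, "stromal": 0.40}
    image, truth, _ = gen_histology(req, seed=11)
    fr = tissue_fractions(segment_tissue(image))
    total = sum(req.values())
    for name, value in fr.as_dict().items():
        assert value == pytest.approx(req[name] / total, abs=0.02)
    assert fr.epithelial + fr.adipose + fr.stromal == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# stains


def test_black_polarised_image_has_zero_birefringence():
    labels = np.full((32, 32), Compartment.STROMAL, dtype=np.uint8)
    mask = SegmentationMask(labels=labels)
    image = np.zeros((32, 32), dtype=np.uint8)
    assert stain_positive_fraction(image, "psr_birefringence", mask) == 0.0


def test_constructed_30_percent_birefringent_fraction():
    labels = np.full((100, 100), Compartment.STROMAL, dtype=np.uint8)
    mask = SegmentationMask(labels=labels)
    image = np.zeros((100, 100))
    image[:30, :] = 0.9  # 30 % of tissue bright under crossed polarisers
    frac = stain_positive_fraction(image, "psr_birefringence", mask)
    assert frac == pytest.approx(0.30)


def test_saturated_image_fraction_is_one():
    labels = np.full((16, 16), Compartment.STROMAL, dtype=np.uint8)
    mask = SegmentationMask(labels=labels)
    assert stain_positive_fraction(np.ones((16, 16)), "psr_birefringence",
                                   mask) == 1.0


def test_masson_collagen_selects_blue_green():
    labels = np.full((32, 32), Compartment.STROMAL, dtype=np.uint8)
    mask = SegmentationMask(labels=labels)
    image = _uniform_rgb((0.5, 0.6, 0.7)).copy()  # blue-green throughout
    assert stain_positive_fraction(image, "masson_collagen", mask) == 1.0
    red = _uniform_rgb((0.02, 0.6, 0.7))
    assert stain_positive_fraction(red, "masson_collagen", mask) == 0.0


def test_roi_disjoint_from_tissue_rejected():
    labels = np.zeros((16, 16), dtype=np.uint8)
    labels[:8] = Compartment.STROMAL
    mask = SegmentationMask(labels=labels)
    roi = np.zeros((16, 16), dtype=bool)
    roi[12:] = True
    with pytest.raises(ValueError):
        stain_positive_fraction(np.ones((16, 16)), "psr_birefringence", mask,
                                roi=roi)


# ---------------------------------------------------------------------------
# peri-ductal band


def test_single_pixel_duct_disc_geometry():
    duct = np.zeros((11, 11), dtype=bool)
    duct[5, 5] = True
    band = periductal_band(duct, pixel_size=10.0, width=20.0)
    yy, xx = np.mgrid[0:11, 0:11]
    dist = np.hypot(yy - 5, xx - 5) * 10.0
    np.testing.assert_array_equal(band, (dist > 0) & (dist <= 20.0))


def test_band_thickness_at_scanner_resolution():
    """20 um at 0.46 um/pixel is a band about 43 pixels thick."""
    duct = np.zeros((120, 120), dtype=bool)
    duct[:, :10] = True
    band = periductal_band(duct, pixel_size=0.46, width=20.0)
    thickness = band[60].sum()
    assert thickness == int(20.0 / 0.46)  # 43 pixels


def test_two_ducts_band_is_union_of_annuli():
    duct_a = np.zeros((40, 40), dtype=bool)
    duct_b = np.zeros((40, 40), dtype=bool)
    duct_a[10, 10] = True
    duct_b[30, 30] = True
    both = duct_a | duct_b
    band_union = periductal_band(duct_a, 10.0, 20.0) | periductal_band(
        duct_b, 10.0, 20.0
    )
    band_both = periductal_band(both, 10.0, 20.0)
    # union of annuli minus any overlap with the other duct's interior
    np.testing.assert_array_equal(band_both, band_union & ~both)


def test_band_monotone_in_width_and_empty_at_zero():
    duct = np.zeros((30, 30), dtype=bool)
    duct[14:16, 14:16] = True
    previous = periductal_band(duct, 1.0, width=0.0)
    assert not previous.any()
    for width in (2.0, 5.0, 9.0, 14.0):
        band = periductal_band(duct, 1.0, width)
        assert (band | previous == band).all()  # superset of the narrower band
        previous = band


def test_empty_duct_mask_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        band = periductal_band(np.zeros((8, 8), dtype=bool), 1.0, 5.0)
    assert not band.any()
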