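"""Histology compartment segmentation by hue/saturation/brightness rules.

Breast tissue sections stained with H&E or Masson's trichrome are
segmented per pixel into background (bare slide glass), adipose,
epithelial and stromal compartments.  The rule operates in HSB colour
space: slide background is bright and unsaturated; among tissue pixels,
epithelium occupies the lowest brightness and hue, adipose the highest,
and stroma the intermediate range.  Brightness cuts may be given
explicitly or derived automatically by three-class Otsu (variance
minimising) thresholding, with hue classes breaking the call for pixels
whose two channels disagree.

Also provided: stain-positive area fractions (Masson collagen, PSR
birefringence) and the peri-ductal band — the stromal annulus within a
fixed distance of duct boundaries where collagen remodelling is assessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.filters import threshold_multiotsu
from skimage.morphology import remove_small_objects

__all__ = [
    "Compartment",
    "SegConfig",
    "SegmentationMask",
    "TissueFractions",
    "segment_tissue",
    "tissue_fractions",
    "stain_positive_fraction",
    "periductal_band",
]


class Compartment(IntEnum):
    BACKGROUND = 0
    EPITHELIAL = 1
    STROMAL = 2
    ADIPOSE = 3


@dataclass(frozen=True)
class SegConfig:
    """Thresholds for the HSB segmentation rule.

    ``brightness_cuts`` and ``hue_cuts`` are each two ascending values in
    [0, 1] splitting tissue pixels into (epithelial | stromal | adipose);
    leave them None for automatic 3-class Otsu selection.  Background is
    any pixel with saturation below ``background_saturation`` and
    brightness above ``background_brightness`` (slide glass).
    """

    brightness_cuts: tuple[float, float] | None = None
    hue_cuts: tuple[float, float] | None = None
    background_saturation: float = 0.08
    background_brightness: float = 0.9
    min_object_px: int = 0  # optional small-object cleanup; 0 = off

    def __post_init__(self) -> None:
        for cuts in (self.brightness_cuts, self.hue_cuts):
            if cuts is not None and not (0 <= cuts[0] < cuts[1] <= 1):
                raise ValueError("cuts must be two ascending values in [0, 1]")


@dataclass(frozen=True)
class SegmentationMask:
    """Per-pixel compartment labels for one histology image."""

    labels: np.ndarray  # values from Compartment
    pixel_size: float = 0.46  # um / pixel

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        valid = set(int(c) for c in Compartment)
        if not set(np.unique(labels)).issubset(valid):
            raise ValueError("labels contain values outside the compartment set")
        object.__setattr__(self, "labels", labels.astype(np.uint8))

    @property
    def tissue(self) -> np.ndarray:
        return self.labels != Compartment.BACKGROUND

    @property
    def is_empty(self) -> bool:
        """True when the image contained no tissue pixels at all."""
        return not bool(self.tissue.any())


@dataclass(frozen=True)
class TissueFractions:
    """Compartment proportions of the tissue (non-background) area."""

    epithelial: float
    adipose: float
    stromal: float
    tissue_area: float  # um^2
    empty: bool = field(default=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "epithelial": self.epithelial,
            "adipose": self.adipose,
            "stromal": self.stromal,
        }


def _to_hsv(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an RGB image (h, w, 3)")
    if image.dtype != np.float64 and np.issubdtype(image.dtype, np.integer):
        image = image / np.iinfo(image.dtype).max
    return rgb2hsv(np.clip(image.astype(float), 0.0, 1.0))


def _three_class(channel: np.ndarray, cuts: tuple[float, float]) -> np.ndarray:
    """0 = below both cuts, 1 = between, 2 = above both."""
    return (channel > cuts[0]).astype(np.int8) + (channel > cuts[1]).astype(np.int8)


def _auto_cuts(values: np.ndarray) -> tuple[float, float]:
    """3-class Otsu cuts; a near-constant channel is made neutral (all
    pixels land in the middle class, so the other channel decides)."""
    if np.unique(values).size < 3:
        return (float(values.min()) - 1.0, float(values.max()) + 1.0)
    lo, hi = threshold_multiotsu(values, classes=3)
    return float(lo), float(hi)


def segment_tissue(
    image: np.ndarray, thresholds: SegConfig | None = None
) -> SegmentationMask:
    """Segment an RGB histology image into the four compartments.

    With automatic thresholds, the two brightness cuts come from 3-class
    Otsu on the brightness of tissue pixels; pixels are classed primarily
    by brightness, and the hue channel (cut the same way) arbitrates when
    the two orderings disagree, per the lowest-epithelial /
    highest-adipose / intermediate-stromal convention.
    """
    config = thresholds or SegConfig()
    hsv = _to_hsv(image)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]

    background = (sat < config.background_saturation) & (
        val > config.background_brightness
    )
    tissue = ~background
    labels = np.zeros(hue.shape, dtype=np.uint8)

    if tissue.any():
        b_cuts = config.brightness_cuts or _auto_cuts(val[tissue])
        h_cuts = config.hue_cuts or _auto_cuts(hue[tissue])
        b_class = _three_class(val, b_cuts)
        h_class = _three_class(hue, h_cuts)
        # brightness leads; hue shifts the call where the channels disagree
        combined = np.round((2.0 * b_class + h_class) / 3.0 + 1e-9).astype(np.int8)
        mapping = np.array(
            [Compartment.EPITHELIAL, Compartment.STROMAL, Compartment.ADIPOSE],
            dtype=np.uint8,
        )
        labels[tissue] = mapping[combined[tissue]]

        if config.min_object_px > 0:
            cleaned = labels.copy()
            for comp in (Compartment.EPITHELIAL, Compartment.STROMAL,
                         Compartment.ADIPOSE):
                keep = remove_small_objects(labels == comp, config.min_object_px)
                cleaned[(labels == comp) & ~keep] = Compartment.STROMAL
            labels = cleaned

    return SegmentationMask(labels=labels)


def tissue_fractions(mask: SegmentationMask) -> TissueFractions:
    """Compartment proportions over the non-background area (sum to 1)."""
    tissue = mask.tissue
    n_tissue = int(tissue.sum())
    area = n_tissue * mask.pixel_size**2
    if n_tissue == 0:
        return TissueFractions(0.0, 0.0, 0.0, 0.0, empty=True)
    counts = np.bincount(mask.labels[tissue], minlength=4)
    return TissueFractions(
        epithelial=counts[Compartment.EPITHELIAL] / n_tissue,
        adipose=counts[Compartment.ADIPOSE] / n_tissue,
        stromal=counts[Compartment.STROMAL] / n_tissue,
        tissue_area=area,
    )


def stain_positive_fraction(
    image: np.ndarray,
    stain: str,
    tissue_mask: SegmentationMask,
    roi: np.ndarray | None = None,
    psr_threshold: float = 0.15,
    masson_hue_band: tuple[float, float] = (0.33, 0.72),
    masson_min_saturation: float = 0.2,
) -> float:
    """Stain-positive pixels as a fraction of tissue pixels within a ROI.

    ``masson_collagen`` selects the blue-green hue band of trichrome-
    positive amorphous collagen; ``psr_birefringence`` thresholds the
    intensity of a crossed-polariser image (birefringent fibres appear
    bright on a dark field).  The PSR intensity threshold is a package
    default — a semiquantitative convention, exposed for adjustment.
    """
    image = np.asarray(image)
    if image.shape[:2] != tissue_mask.labels.shape:
        raise ValueError("image and tissue mask shapes differ")
    region = tissue_mask.tissue
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != region.shape:
            raise ValueError("roi shape must match the mask")
        region = region & roi
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("ROI contains no tissue pixels")

    if stain == "masson_collagen":
        hsv = _to_hsv(image)
        positive = (
            (hsv[..., 0] >= masson_hue_band[0])
            & (hsv[..., 0] <= masson_hue_band[1])
            & (hsv[..., 1] >= masson_min_saturation)
        )
    elif stain == "psr_birefringence":
        gray = image.astype(float)
        if gray.ndim == 3:
            gray = gray.mean(axis=-1)
        if np.issubdtype(image.dtype, np.integer):
            gray = gray / np.iinfo(image.dtype).max
        positive = gray > psr_threshold
    else:
        raise ValueError(f"unknown stain {stain!r}")
    return float(positive[region].sum() / n_region)


def periductal_band(
    duct_mask: np.ndarray, pixel_size: float, width: float = 20.0
) -> np.ndarray:
    """Pixels within ``width`` um of a duct, excluding the duct itself.

    The band is the Euclidean-distance annulus (0, width] around the duct
    mask — the peri-ductal stroma in which fibrillar collagen organisation
    is scored.  Multiple ducts yield the union of their annuli.
    """
    duct_mask = np.asarray(duct_mask, dtype=bool)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if width <= 0:
        return np.zeros_like(duct_mask)
    if not duct_mask.any():
        warnings.warn("duct mask is empty; returning an empty band", stacklevel=2)
        return np.zeros_like(duct_mask)
    dist = ndimage.distance_transform_edt(~duct_mask, sampling=pixel_size)
    return (dist > 0) & (dist <= width)
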