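"""HSV threshold-mask cell segmentation.

The segmenter isolates the stained leukocyte from the pale smear background
in five steps: convert RGB to HSV, build three binary threshold masks (a
lower-hue mask keeping hue >= lower bound, an upper-hue mask keeping hue <=
upper bound, and a saturation mask keeping saturation >= a minimum), multiply
the masks, clean the result morphologically (binary opening to remove speckle
then closing to fill holes), and zero the background in every RGB channel.

All hue/saturation thresholds live on [0, 1]. Hue bounds are a plain interval
— no wraparound across the 0/1 red seam — which matches the stain palette
(blue through magenta). For neutrophils the hue interval is the full [0.0,
1.0] range and the saturation minimum is 0.45, so saturation alone separates
the stained cell from the desaturated background; the other three classes
ship with hue intervals tuned on the synthetic generator (documented,
non-canonical defaults).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb as _sk_hsv2rgb
from skimage.color import rgb2hsv as _sk_rgb2hsv
from skimage.morphology import closing as _closing
from skimage.morphology import disk
from skimage.morphology import opening as _opening

from .cells import CellClass


@dataclass(frozen=True)
class HsvThresholds:
    """Hue interval + saturation floor driving the three threshold masks."""

    lower_hue: float
    upper_hue: float
    saturation_min: float

    def __post_init__(self) -> None:
        for f in ("lower_hue", "upper_hue", "saturation_min"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if self.lower_hue > self.upper_hue:
            raise ValueError(
                f"lower_hue ({self.lower_hue}) must be <= upper_hue ({self.upper_hue})"
            )


#: Per-class defaults. Neutrophil carries the canonical (0.0, 1.0, 0.45)
#: setting; the other intervals bracket each class's stain hues as rendered by
#: the synthetic generator.
DEFAULT_THRESHOLDS: dict[str, HsvThresholds] = {
    "eosinophil": HsvThresholds(0.72, 0.98, 0.45),
    "lymphocyte": HsvThresholds(0.66, 0.84, 0.45),
    "monocyte": HsvThresholds(0.48, 0.68, 0.45),
    "neutrophil": HsvThresholds(0.0, 1.0, 0.45),
}


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray        # (H, W) uint8 in {0, 1}
    segmented: np.ndarray   # (H, W, 3) input with background zeroed
    thresholds: HsvThresholds
    morphology_radius: int


def thresholds_for(cell_class: CellClass | str) -> HsvThresholds:
    name = cell_class.name if isinstance(cell_class, CellClass) else str(cell_class).lower()
    if name not in DEFAULT_THRESHOLDS:
        raise ValueError(
            f"unknown cell class {cell_class!r}; valid classes are {sorted(DEFAULT_THRESHOLDS)}"
        )
    return DEFAULT_THRESHOLDS[name]


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Hexcone RGB -> HSV with all three channels on [0, 1]."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError(
            f"RGB values must lie in [0, 1]; got range [{image.min()}, {image.max()}]"
        )
    return _sk_rgb2hsv(image)


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse conversion, for round-trip checks and visualization."""
    return _sk_hsv2rgb(np.asarray(hsv, dtype=float))


def threshold_masks(hsv: np.ndarray, t: HsvThresholds):
    """Lower-hue, upper-hue and saturation masks as uint8 0/1 arrays."""
    hue = hsv[..., 0]
    sat = hsv[..., 1]
    lower = (hue >= t.lower_hue).astype(np.uint8)
    upper = (hue <= t.upper_hue).astype(np.uint8)
    saturation = (sat >= t.saturation_min).astype(np.uint8)
    return lower, upper, saturation


def combine_masks(lower: np.ndarray, upper: np.ndarray, saturation: np.ndarray) -> np.ndarray:
    """Elementwise product of the three masks (logical AND on 0/1 inputs)."""
    lower, upper, saturation = (np.asarray(m) for m in (lower, upper, saturation))
    if not lower.shape == upper.shape == saturation.shape:
        raise ValueError(
            f"mask shapes differ: {lower.shape}, {upper.shape}, {saturation.shape}"
        )
    return (lower * upper * saturation).astype(np.uint8)


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Multiply each RGB channel by the mask, zeroing the background."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"spatial shapes differ: image {image.shape[:2]} vs mask {mask.shape}"
        )
    return image * mask[..., None]


def morphological_cleanup(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary opening then closing with a disk element; radius 0 is identity."""
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    mask = np.asarray(mask).astype(bool)
    if radius == 0:
        return mask.astype(np.uint8)
    selem = disk(radius)
    opened = _opening(mask, selem)
    closed = _closing(opened, selem)
    return closed.astype(np.uint8)


def segment(image: np.ndarray, t: HsvThresholds, radius: int = 2) -> SegmentationResult:
    """Full threshold-mask segmentation of one RGB smear image."""
    hsv = rgb_to_hsv(image)
    lower, upper, saturation = threshold_masks(hsv, t)
    mask = combine_masks(lower, upper, saturation)
    mask = morphological_cleanup(mask, radius)
    segmented = apply_mask(np.asarray(image, dtype=float), mask)
    return SegmentationResult(mask=mask, segmented=segmented,
                              thresholds=t, morphology_radius=radius)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (1.0 if both empty)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
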