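"""Bulk tea shoot detection in RGB canopy images.

Young shoots are bright green against darkened older leaves, so a
super-green (excess-green) index ``2G - R/2 - B`` turns the frame into a
near-bimodal grayscale image that Otsu's method can threshold. Field
illumination varies widely, so frames are first classified by their average
grayscale (AG) into a low-light band [90, 140) and a high-light band
[140, 220] and processed by two different branches:

* low light: CLAHE contrast enhancement, then super-green + Otsu;
* high light: specular highlights are masked to gray 0 first, then
  super-green + Otsu restricted to nonzero levels, with the specular
  pixels forced to background.

Both branches finish with a morphological erosion that removes isolated
small responses. Instance-level separation of individual shoots is out of
scope: the mask only needs to select shoot pixels whose depths are then
averaged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .clahe import clahe_gray
from .errors import (
    DegenerateHistogramError,
    LightingOutOfRangeError,
    ParameterError,
)
from .regions import RegionSpec

#: ITU-R BT.601 luma weights used for the AG (average grayscale) statistic.
_LUMA = np.array([0.299, 0.587, 0.114])


class Lighting(enum.Enum):
    LOW_LIGHT = "low_light"
    HIGH_LIGHT = "high_light"
    OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class LightingClass:
    """Lighting-band assignment of a frame plus the AG value behind it."""

    label: Lighting
    ag_value: float


@dataclass(frozen=True)
class ShootMask:
    """Binary per-pixel shoot labelling plus the lighting branch that made it."""

    pixels: np.ndarray  # bool, H x W
    source_lighting: LightingClass

    def __post_init__(self) -> None:
        if self.pixels.dtype != bool or self.pixels.ndim != 2:
            raise ParameterError("ShootMask.pixels must be a 2-D boolean array")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable knobs of the segmentation branches.

    ``ag_low``/``ag_mid``/``ag_high`` delimit the lighting bands
    [ag_low, ag_mid) and [ag_mid, ag_high]. The specular rule marks pixels
    whose *minimum* channel is at least ``specular_threshold`` — saturated
    highlights are bright in all three channels.
    """

    clahe_clip_limit: float = 2.0
    clahe_tile: int = 8
    specular_threshold: int = 230
    erosion_kernel: int = 3
    erosion_iterations: int = 1
    ag_low: float = 90.0
    ag_mid: float = 140.0
    ag_high: float = 220.0

    def __post_init__(self) -> None:
        if not (self.ag_low < self.ag_mid <= self.ag_high):
            raise ParameterError("require ag_low < ag_mid <= ag_high")
        if self.erosion_kernel < 1 or self.erosion_kernel % 2 == 0:
            raise ParameterError("erosion_kernel must be odd and >= 1")
        if self.clahe_tile < 1:
            raise ParameterError("clahe_tile must be >= 1")


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ParameterError("expected a non-empty H x W x 3 RGB image")
    return image


def average_gray(image: np.ndarray, region: RegionSpec | None = None) -> float:
    """Mean luminance (AG value) of the frame, optionally over a sub-region.

    The canopy fills the frame in this rig, so by default AG is taken over
    all pixels; pass ``region`` to restrict it.
    """
    image = _validate_rgb(image)
    if region is not None:
        rs, cs = region.to_slices(image.shape)
        image = image[rs, cs]
    return float(np.mean(image.astype(np.float64) @ _LUMA))


def classify_lighting(ag: float, cfg: SegmentationConfig | None = None) -> LightingClass:
    """Assign a frame's AG value to the low-light or high-light band.

    Bands are [ag_low, ag_mid) and [ag_mid, ag_high]; anything else is
    OUT_OF_RANGE (a value, not an error — the pipeline decides what to do).
    """
    cfg = cfg or SegmentationConfig()
    if not 0.0 <= ag <= 255.0:
        raise ParameterError(f"AG value {ag} outside [0, 255]")
    if cfg.ag_low <= ag < cfg.ag_mid:
        label = Lighting.LOW_LIGHT
    elif cfg.ag_mid <= ag <= cfg.ag_high:
        label = Lighting.HIGH_LIGHT
    else:
        label = Lighting.OUT_OF_RANGE
    return LightingClass(label=label, ag_value=float(ag))


def supergreen(image: np.ndarray) -> np.ndarray:
    """Super-green index image: per pixel ``clamp(2G - R/2 - B, 0, 255)``.

    Arithmetic is done in floating point (R/2 is exact halving) before
    clamping and quantizing to uint8.
    """
    image = _validate_rgb(image).astype(np.float64)
    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    sg = 2.0 * g - r / 2.0 - b
    return np.clip(np.floor(sg + 0.5), 0, 255).astype(np.uint8)


def clahe_enhance(image: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """CLAHE on the luminance channel of an RGB image, chromaticity preserved.

    The image is taken to YCbCr, the luma plane is equalized with the
    configured clip limit and tile grid, and the chroma planes are carried
    through unchanged.
    """
    from skimage import color

    cfg = cfg or SegmentationConfig()
    image = _validate_rgb(image)
    ycbcr = color.rgb2ycbcr(image.astype(np.float64) / 255.0)
    y = np.clip(np.rint(ycbcr[..., 0]), 0, 255).astype(np.uint8)
    ycbcr[..., 0] = clahe_gray(y, cfg.clahe_clip_limit, cfg.clahe_tile).astype(np.float64)
    rgb = color.ycbcr2rgb(ycbcr)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def specular_mask(image: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Boolean mask of specular-highlight pixels.

    A pixel is specular when all three channels are at least the configured
    threshold (default 230): direct-sun highlights saturate every channel.
    """
    cfg = cfg or SegmentationConfig()
    image = _validate_rgb(image)
    return image.min(axis=2) >= cfg.specular_threshold


def otsu_threshold(gray: np.ndarray, exclude_zero: bool = False) -> int:
    """Otsu's threshold: the gray level maximizing between-class variance.

    A threshold ``t`` splits levels into {<= t} and {> t}. With
    ``exclude_zero`` the zero bin is dropped from the histogram so masked
    (specular) pixels never influence the split. Ties break toward the
    lower threshold.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ParameterError("empty grayscale image")
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if hist.size > 256:
        raise ParameterError("otsu_threshold expects 8-bit data")
    if exclude_zero:
        hist[0] = 0.0
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "need at least two distinct eligible gray levels"
        )
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    s0 = np.cumsum(hist * levels)
    total, s_total = w0[-1], s0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    var_b = np.full(256, -1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean0 = s0 / w0
        mean1 = (s_total - s0) / w1
        var_b[valid] = (w0 * w1 * (mean0 - mean1) ** 2)[valid]
    return int(np.argmax(var_b))


def morphological_erode(mask: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Binary erosion with a square structuring element, repeated as configured."""
    cfg = cfg or SegmentationConfig()
    mask = np.asarray(mask, dtype=bool)
    if cfg.erosion_iterations < 1:
        return mask.copy()
    footprint = np.ones((cfg.erosion_kernel, cfg.erosion_kernel), dtype=bool)
    return ndimage.binary_erosion(
        mask, structure=footprint, iterations=cfg.erosion_iterations, border_value=0
    )


def segment_shoots(
    image: np.ndarray,
    cfg: SegmentationConfig | None = None,
    force_class: Lighting | None = None,
) -> ShootMask:
    """Full shoot-segmentation pipeline dispatching on the lighting class.

    Low light: CLAHE -> super-green -> Otsu over all pixels -> erode.
    High light: mask specular pixels to 0 -> super-green -> zero-excluding
    Otsu -> erode, specular pixels forced to background.

    ``force_class`` overrides the AG-based dispatch (for frames whose AG
    falls outside both bands); otherwise an out-of-range AG raises
    :class:`LightingOutOfRangeError`.
    """
    cfg = cfg or SegmentationConfig()
    image = _validate_rgb(image)
    lighting = classify_lighting(average_gray(image), cfg)
    label = force_class or lighting.label
    if label is Lighting.LOW_LIGHT:
        enhanced = clahe_enhance(image, cfg)
        sg = supergreen(enhanced)
        thr = otsu_threshold(sg, exclude_zero=False)
        fg = sg > thr
    elif label is Lighting.HIGH_LIGHT:
        spec = specular_mask(image, cfg)
        work = image.copy()
        work[spec] = 0
        sg = supergreen(work)
        thr = otsu_threshold(sg, exclude_zero=True)
        fg = sg > thr
        fg[spec] = False
    else:
        raise LightingOutOfRangeError(
            f"AG {lighting.ag_value:.1f} outside the configured lighting bands"
        )
    fg = morphological_erode(fg, cfg)
    if label is Lighting.HIGH_LIGHT:
        fg &= ~spec
    return ShootMask(pixels=fg, source_lighting=lighting)
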