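"""Depth preprocessing and region-averaged shoot depths (l_near, l_far).

Depth rasters arrive in millimetres with 0 as the invalid sentinel (holes,
dropped returns). Preprocessing gates values to a plausible camera-to-canopy
range and median-smooths over valid pixels only. The pose computation then
needs two scalars: the mean shoot depth inside a central region (l_near) and
inside a left-edge region (l_far). Restricting the average to segmented
shoot pixels matters because older leaves sit several centimetres deeper and
would bias a whole-region mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientEvidenceError, ParameterError
from .regions import FAR_REGION, NEAR_REGION, RegionSpec
from .segmentation import ShootMask

#: Invalid-depth sentinel (mm), shared with the synthetic generator.
INVALID_DEPTH = 0


@dataclass(frozen=True)
class DepthFilterConfig:
    """Plausibility gate and smoothing for raw depth rasters.

    The gate default [200, 2000] mm brackets the camera heights this rig
    operates at (~450-750 mm above the canopy) with wide margins.
    """

    min_depth_mm: float = 200.0
    max_depth_mm: float = 2000.0
    median_kernel: int = 5
    min_valid_pixels: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.min_depth_mm < self.max_depth_mm:
            raise ParameterError("require 0 < min_depth_mm < max_depth_mm")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ParameterError("median_kernel must be odd and >= 1")
        if self.min_valid_pixels < 1:
            raise ParameterError("min_valid_pixels must be >= 1")


@dataclass(frozen=True)
class CanopyFrame:
    """A pixel-aligned RGB + depth observation of the canopy top."""

    rgb: np.ndarray  # uint8, H x W x 3
    depth: np.ndarray  # mm, H x W
    frame_id: str = ""
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if self.rgb.shape[:2] != self.depth.shape:
            raise ParameterError(
                f"rgb {self.rgb.shape[:2]} and depth {self.depth.shape} not aligned"
            )


def _validate_depth(depth: np.ndarray) -> np.ndarray:
    depth = np.asarray(depth)
    if depth.ndim != 2 or depth.size == 0:
        raise ParameterError("expected a non-empty 2-D depth raster")
    return depth


def filter_depth(depth: np.ndarray, cfg: DepthFilterConfig | None = None) -> np.ndarray:
    """Set pixels outside [min_depth_mm, max_depth_mm] to the invalid sentinel."""
    cfg = cfg or DepthFilterConfig()
    depth = _validate_depth(depth)
    out = depth.copy()
    bad = (depth < cfg.min_depth_mm) | (depth > cfg.max_depth_mm)
    out[bad] = INVALID_DEPTH
    return out


def median_smooth(depth: np.ndarray, cfg: DepthFilterConfig | None = None) -> np.ndarray:
    """Median filter over valid pixels only.

    Invalid pixels are excluded from every window and remain invalid in the
    output; a valid pixel whose window contains invalids takes the median of
    the valid subset.
    """
    cfg = cfg or DepthFilterConfig()
    depth = _validate_depth(depth)
    k = cfg.median_kernel
    if k == 1:
        return depth.copy()
    pad = k // 2
    work = depth.astype(np.float64)
    work[depth == INVALID_DEPTH] = np.nan
    padded = np.pad(work, pad, mode="constant", constant_values=np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (k, k))
    with np.errstate(all="ignore"):
        med = np.nanmedian(windows.reshape(*depth.shape, k * k), axis=-1)
    out = np.where(np.isnan(med), INVALID_DEPTH, med)
    out[depth == INVALID_DEPTH] = INVALID_DEPTH
    if np.issubdtype(depth.dtype, np.integer):
        out = np.rint(out)
    return out.astype(depth.dtype)


def region_mean_depth(
    depth: np.ndarray,
    mask: ShootMask | np.ndarray | None,
    region: RegionSpec,
    cfg: DepthFilterConfig | None = None,
) -> float:
    """Mean depth (cm) of valid shoot pixels inside a region rectangle.

    Contributing pixels must be (a) inside the region, (b) shoot foreground
    in ``mask`` (pass ``None`` for a whole-region mean), and (c) valid.
    Raises :class:`InsufficientEvidenceError` when fewer than
    ``min_valid_pixels`` pixels contribute.
    """
    cfg = cfg or DepthFilterConfig()
    depth = _validate_depth(depth)
    if isinstance(mask, ShootMask):
        mask = mask.pixels
    rs, cs = region.to_slices(depth.shape)
    patch = depth[rs, cs]
    sel = patch != INVALID_DEPTH
    if mask is not None:
        if mask.shape != depth.shape:
            raise ParameterError("mask not aligned with depth raster")
        sel &= mask[rs, cs].astype(bool)
    n = int(sel.sum())
    if n < cfg.min_valid_pixels:
        raise InsufficientEvidenceError(
            f"only {n} valid shoot pixels in region (need {cfg.min_valid_pixels})"
        )
    return float(patch[sel].mean()) / 10.0


def extract_l_values(
    frame: CanopyFrame,
    mask: ShootMask | np.ndarray,
    near_region: RegionSpec = NEAR_REGION,
    far_region: RegionSpec = FAR_REGION,
    cfg: DepthFilterConfig | None = None,
    allow_fallback: bool = True,
) -> tuple[float, float, dict]:
    """Preprocess the depth raster and return (l_near, l_far) in cm.

    Runs gate -> median smoothing once, then averages each region. When a
    region holds too few shoot pixels and ``allow_fallback`` is set, the
    whole-region valid-pixel mean is used instead and flagged in the
    returned info dict (the rig must still produce a pose every frame).
    """
    cfg = cfg or DepthFilterConfig()
    smoothed = median_smooth(filter_depth(frame.depth, cfg), cfg)
    info: dict = {"fallback": {}}
    values = []
    for name, region in (("near", near_region), ("far", far_region)):
        try:
            value = region_mean_depth(smoothed, mask, region, cfg)
            info["fallback"][name] = False
        except InsufficientEvidenceError:
            if not allow_fallback:
                raise
            value = region_mean_depth(smoothed, None, region, cfg)
            info["fallback"][name] = True
        values.append(value)
    return values[0], values[1], info
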