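"""Seeded synthetic RGB-D canopy frames with exact ground truth.

No public field dataset exists for this task, so every downstream stage is
exercised on generated frames that emulate what the rig's nadir-mounted
RGB-D camera sees:

* bright-green shoot blobs (overlapping ellipses with per-blob jitter) over
  a darker old-leaf background with low-frequency texture;
* an arc-shaped canopy depth profile — depth(x) = peak + sag * u^2 + tilt * t
  with u the normalized offset from the image centre line and t the
  normalized column — plus Gaussian depth noise, invalid-depth holes, and
  old leaves sitting a fixed offset below the shoot surface;
* a global illumination gain calibrated by bisection so the frame's AG
  value lands inside the requested lighting band, and optional saturated
  specular patches for the high-light branch.

The generator also returns the exact ground truth (shoot mask, the true
region-averaged depths l_near / l_far from the noise-free surface, and the
implied true pose), which parameter-recovery tests compare against.

The texture statistics are free choices — only the documented invariants
(channel ordering, AG band, depth geometry) are claimed to match reality.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .depth import INVALID_DEPTH, CanopyFrame
from .errors import ParameterError
from .pose import RigConfig, compute_alpha, compute_d
from .regions import FAR_REGION, NEAR_REGION, RegionSpec
from .segmentation import _LUMA

#: AG calibration targets, centred in each lighting band (cf. field frames
#: whose AG ran 115-124 under overcast/cloudy skies and 166-171 in sun).
_AG_TARGET = {"low": 120.0, "high": 168.0}
_AG_BAND = {"low": (90.0, 140.0), "high": (140.0, 220.0)}
_SPECULAR_VALUE = 248

#: Shoot-cluster ellipse semi-axis ranges (px). At the rig's nadir geometry
#: (~5 px/cm at 320 px width) these are 5-10 cm clusters of stacked shoots;
#: bulk shoots blanket most of the canopy top, hence the high default density.
_SHOOT_AXES = (12.0, 26.0, 7.0, 15.0)


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the synthetic canopy scene.

    Lengths are cm except ``depth_noise_sd`` (mm). ``shoot_density`` is the
    target fraction of pixels covered by shoot blobs; a value >= 0.999 means
    a full canopy (every pixel is shoot), which makes the regional truth an
    exact integral of the arc surface.
    """

    image_height: int = 240
    image_width: int = 320
    canopy_arc_peak_depth: float = 45.0
    canopy_arc_sag: float = 6.0
    tilt: float = 0.0
    shoot_density: float = 0.8
    shoot_green_level: int = 190
    old_leaf_darkening: float = 0.45
    old_leaf_depth_offset: float = 8.0
    illumination: str = "low"
    specular_fraction: float = 0.0
    depth_noise_sd: float = 3.0
    hole_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise ParameterError("image dimensions must be at least 64x64")
        for name in ("shoot_density", "specular_fraction", "hole_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.canopy_arc_peak_depth <= 0:
            raise ParameterError("canopy_arc_peak_depth must be positive")
        if not 0.0 < self.old_leaf_darkening < 1.0:
            raise ParameterError("old_leaf_darkening must lie in (0, 1)")
        if self.illumination not in ("low", "high"):
            raise ParameterError("illumination must be 'low' or 'high'")
        if self.depth_noise_sd < 0 or self.old_leaf_depth_offset < 0:
            raise ParameterError("noise and depth offset must be non-negative")
        if not 0 < self.shoot_green_level <= 255:
            raise ParameterError("shoot_green_level must be in (0, 255]")


@dataclass(frozen=True)
class GroundTruth:
    """Exact scene truth for parameter-recovery tests."""

    shoot_mask: np.ndarray  # bool, visible (non-specular) shoot pixels
    true_l_near: float  # cm
    true_l_far: float  # cm
    true_d: float  # cm
    true_alpha: float  # degrees


def surface_depth_cm(params: SceneParams) -> np.ndarray:
    """Noise-free canopy-surface depth (cm) per column, shape (W,)."""
    w = params.image_width
    x = np.arange(w, dtype=np.float64)
    u = (x - (w - 1) / 2.0) / ((w - 1) / 2.0)  # -1 at left edge, +1 at right
    t = x / (w - 1) - 0.5  # -0.5 .. +0.5 left to right
    return (
        params.canopy_arc_peak_depth
        + params.canopy_arc_sag * u**2
        + params.tilt * t
    )


def _leaf_texture(rng: np.random.Generator, shape: tuple[int, int], cells: int = 8) -> np.ndarray:
    """Multiplicative old-leaf texture around 1.0.

    A gentle low-frequency shading field plus strong per-pixel speckle: leaf
    surfaces are locally rough, so most of the background's contrast lives at
    the pixel scale (isolated responses a small erosion removes) rather than
    in large connected patches.
    """
    grid = rng.uniform(0.97, 1.03, size=(cells, cells))
    zoom = (shape[0] / cells, shape[1] / cells)
    fld = ndimage.zoom(grid, zoom, order=1)[: shape[0], : shape[1]]
    speckle = rng.normal(1.0, 0.08, size=shape)
    return np.clip(fld * speckle, 0.5, 1.5)


def _stamp_ellipses(
    rng: np.random.Generator,
    shape: tuple[int, int],
    target_fraction: float,
    value_jitter: tuple[float, float],
    axis_range: tuple[float, float, float, float],
    max_blobs: int = 20000,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate random rotated ellipses until coverage reaches the target.

    Returns the coverage mask and a per-pixel jitter map (last blob wins).
    """
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    jitter = np.ones(shape, dtype=np.float64)
    target = target_fraction * h * w
    covered = 0
    a_lo, a_hi, b_lo, b_hi = axis_range
    for _ in range(max_blobs):
        if covered >= target:
            break
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sa, sb = rng.uniform(a_lo, a_hi), rng.uniform(b_lo, b_hi)
        theta = rng.uniform(0, math.pi)
        jit = rng.uniform(*value_jitter)
        rad = int(math.ceil(max(sa, sb))) + 1
        y0, y1 = max(0, int(cy) - rad), min(h, int(cy) + rad + 1)
        x0, x1 = max(0, int(cx) - rad), min(w, int(cx) + rad + 1)
        if y1 <= y0 or x1 <= x0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        ct, st = math.cos(theta), math.sin(theta)
        e = ((dx * ct + dy * st) / sa) ** 2 + ((-dx * st + dy * ct) / sb) ** 2 <= 1.0
        patch = mask[y0:y1, x0:x1]
        covered += int((e & ~patch).sum())
        patch |= e
        jitter[y0:y1, x0:x1][e] = jit
    return mask, jitter


def _render_rgb(base: np.ndarray, gain: float, spec_mask: np.ndarray) -> np.ndarray:
    out = np.clip(base * gain, 0.0, 255.0)
    out[spec_mask] = _SPECULAR_VALUE
    return np.floor(out + 0.5).astype(np.uint8)


def _calibrate_gain(base: np.ndarray, spec_mask: np.ndarray, target_ag: float) -> float:
    """Deterministic bisection for the global gain hitting the target AG."""
    def ag(gain: float) -> float:
        img = _render_rgb(base, gain, spec_mask)
        return float(np.mean(img.astype(np.float64) @ _LUMA))

    lo, hi = 0.05, 8.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if ag(mid) < target_ag:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_frame(
    params: SceneParams,
    rig: RigConfig | None = None,
    near_region: RegionSpec = NEAR_REGION,
    far_region: RegionSpec = FAR_REGION,
) -> tuple[CanopyFrame, GroundTruth]:
    """Render one synthetic RGB-D canopy frame plus its exact ground truth.

    All randomness flows from one ``numpy`` generator seeded with
    ``params.seed``, so identical parameters give bit-identical frames.
    Truth depths are area-weighted means of the *noise-free* surface over
    visible shoot pixels inside each region (NaN if a region holds none).
    """
    rig = rig or RigConfig()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    shape = (h, w)

    # -- geometry -----------------------------------------------------------
    surf_cm = np.broadcast_to(surface_depth_cm(params), shape)

    # -- shoot layout -------------------------------------------------------
    if params.shoot_density >= 0.999:
        shoot = np.ones(shape, dtype=bool)
        shoot_jit = np.ones(shape)
        _ = rng.uniform()  # keep the stream aligned with the blob branch
    elif params.shoot_density <= 0.0:
        shoot = np.zeros(shape, dtype=bool)
        shoot_jit = np.ones(shape)
        _ = rng.uniform()
    else:
        shoot, shoot_jit = _stamp_ellipses(
            rng, shape, params.shoot_density, (0.88, 1.05), _SHOOT_AXES
        )

    # -- colour -------------------------------------------------------------
    bg_field = _leaf_texture(rng, shape)
    g_level = float(params.shoot_green_level)
    base = np.empty((h, w, 3), dtype=np.float64)
    g_bg = g_level * params.old_leaf_darkening * bg_field
    base[..., 0] = 0.55 * g_bg
    base[..., 1] = g_bg
    base[..., 2] = 0.45 * g_bg
    g_sh = np.clip(g_level * shoot_jit, 0, 255)
    base[..., 0][shoot] = 0.45 * g_sh[shoot]
    base[..., 1][shoot] = g_sh[shoot]
    base[..., 2][shoot] = 0.35 * g_sh[shoot]

    # -- specular patches ---------------------------------------------------
    if params.specular_fraction > 0:
        spec, _ = _stamp_ellipses(
            rng, shape, params.specular_fraction, (1.0, 1.0), (2.5, 6.0, 2.0, 5.0)
        )
    else:
        spec = np.zeros(shape, dtype=bool)

    # -- illumination -------------------------------------------------------
    gain = _calibrate_gain(base, spec, _AG_TARGET[params.illumination])
    rgb = _render_rgb(base, gain, spec)
    ag = float(np.mean(rgb.astype(np.float64) @ _LUMA))
    lo, hi = _AG_BAND[params.illumination]
    if not lo <= ag <= hi:
        raise ParameterError(
            f"generator self-check failed: AG {ag:.1f} outside {params.illumination} band"
        )

    # -- depth --------------------------------------------------------------
    depth_true_mm = surf_cm * 10.0 + (~shoot) * (params.old_leaf_depth_offset * 10.0)
    depth = depth_true_mm + rng.normal(0.0, params.depth_noise_sd, size=shape)
    depth = np.clip(np.rint(depth), 1, 65535).astype(np.uint16)
    if params.hole_fraction > 0:
        holes = rng.random(shape) < params.hole_fraction
        depth[holes] = INVALID_DEPTH

    # -- ground truth -------------------------------------------------------
    visible = shoot & ~spec
    l_values = []
    for region in (near_region, far_region):
        rs, cs = region.to_slices(shape)
        sel = visible[rs, cs]
        if sel.any():
            l_values.append(float(depth_true_mm[rs, cs][sel].mean()) / 10.0)
        else:
            l_values.append(float("nan"))
    true_l_near, true_l_far = l_values
    true_d = compute_d(rig, true_l_near) if math.isfinite(true_l_near) else float("nan")
    true_alpha = compute_alpha(rig, true_l_far) if math.isfinite(true_l_far) else float("nan")

    frame = CanopyFrame(rgb=rgb, depth=depth, frame_id=f"synthetic-{params.seed}")
    truth = GroundTruth(
        shoot_mask=visible,
        true_l_near=true_l_near,
        true_l_far=true_l_far,
        true_d=true_d,
        true_alpha=true_alpha,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# Fixture persistence
# ---------------------------------------------------------------------------


def write_fixture(
    frame: CanopyFrame,
    truth: GroundTruth,
    directory: str | Path,
    params: SceneParams | None = None,
) -> Path:
    """Persist a frame + truth as PNGs and a JSON manifest; returns the manifest path.

    RGB as 8-bit PNG, depth as 16-bit single-channel PNG (mm), mask as 8-bit
    {0, 255} PNG. The manifest records the scene parameters (including the
    seed), so the fixture can be regenerated bit-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / "rgb.png", frame.rgb)
    iio.imwrite(directory / "depth.png", frame.depth.astype(np.uint16))
    iio.imwrite(directory / "mask.png", truth.shoot_mask.astype(np.uint8) * 255)
    manifest = {
        "frame_id": frame.frame_id,
        "files": {"rgb": "rgb.png", "depth": "depth.png", "mask": "mask.png"},
        "truth": {
            "true_l_near": truth.true_l_near,
            "true_l_far": truth.true_l_far,
            "true_d": truth.true_d,
            "true_alpha": truth.true_alpha,
        },
        "params": dataclasses.asdict(params) if params is not None else None,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_fixture(directory: str | Path) -> tuple[CanopyFrame, GroundTruth, SceneParams | None]:
    """Load a fixture written by :func:`write_fixture` (exact round-trip)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    rgb = iio.imread(directory / manifest["files"]["rgb"])
    depth = iio.imread(directory / manifest["files"]["depth"]).astype(np.uint16)
    mask = iio.imread(directory / manifest["files"]["mask"]) > 0
    t = manifest["truth"]
    frame = CanopyFrame(rgb=rgb, depth=depth, frame_id=manifest.get("frame_id", ""))
    truth = GroundTruth(
        shoot_mask=mask,
        true_l_near=t["true_l_near"],
        true_l_far=t["true_l_far"],
        true_d=t["true_d"],
        true_alpha=t["true_alpha"],
    )
    params = SceneParams(**manifest["params"]) if manifest.get("params") else None
    return frame, truth, params
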