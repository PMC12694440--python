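"""Contrast-limited adaptive histogram equalization (CLAHE).

Uses the classic tile-based formulation: the frame is divided into a grid of
tiles, each tile gets a clipped, renormalized histogram-equalization lookup
table, and every pixel is remapped by bilinearly blending the LUTs of the
four surrounding tile centres. The clip limit is expressed as a multiple of
the mean histogram bin count (so ``clip_limit=2.0`` clips every bin at twice
the uniform level), which is the convention the method's configuration
values use.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

_N_BINS = 256


def _tile_luts(tiles: np.ndarray, clip_limit: float) -> np.ndarray:
    """Equalization LUTs for a (gh, gw, th, tw) stack of uint8 tiles."""
    gh, gw, th, tw = tiles.shape
    area = th * tw
    flat = tiles.reshape(gh * gw, area)
    hist = np.zeros((gh * gw, _N_BINS), dtype=np.float64)
    for i in range(gh * gw):
        hist[i] = np.bincount(flat[i], minlength=_N_BINS)
    if clip_limit > 0:
        clip = max(clip_limit * area / _N_BINS, 1.0)
        excess = np.clip(hist - clip, 0.0, None).sum(axis=1, keepdims=True)
        hist = np.minimum(hist, clip) + excess / _N_BINS
    cdf = np.cumsum(hist, axis=1)
    luts = np.rint(cdf * (_N_BINS - 1) / area)
    return np.clip(luts, 0, 255).reshape(gh, gw, _N_BINS)


def clahe_gray(gray: np.ndarray, clip_limit: float = 2.0, grid: int = 8) -> np.ndarray:
    """Apply CLAHE to a 2-D uint8 image using a ``grid`` × ``grid`` tile grid.

    Parameters
    ----------
    gray:
        2-D uint8 array.
    clip_limit:
        Histogram clip level as a multiple of the mean bin count; values
        <= 0 disable clipping (plain adaptive equalization).
    grid:
        Number of tiles along each axis.

    Returns
    -------
    2-D uint8 array of the same shape.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ParameterError("clahe_gray expects a 2-D grayscale image")
    h, w = gray.shape
    if h < grid or w < grid:
        raise ParameterError(
            f"image {h}x{w} smaller than the {grid}x{grid} tile grid"
        )
    th = -(-h // grid)  # ceil
    tw = -(-w // grid)
    ph, pw = th * grid - h, tw * grid - w
    padded = np.pad(gray, ((0, ph), (0, pw)), mode="reflect")
    tiles = padded.reshape(grid, th, grid, tw).transpose(0, 2, 1, 3)
    luts = _tile_luts(tiles.astype(np.uint8), clip_limit)

    rows = np.arange(h)
    cols = np.arange(w)
    ty = (rows + 0.5) / th - 0.5
    tx = (cols + 0.5) / tw - 0.5
    i0 = np.clip(np.floor(ty).astype(int), 0, grid - 1)
    j0 = np.clip(np.floor(tx).astype(int), 0, grid - 1)
    i1 = np.clip(i0 + 1, 0, grid - 1)
    j1 = np.clip(j0 + 1, 0, grid - 1)
    wy = np.clip(ty - np.floor(ty), 0.0, 1.0)[:, None]
    wx = np.clip(tx - np.floor(tx), 0.0, 1.0)[None, :]

    img = gray
    v00 = luts[i0[:, None], j0[None, :], img]
    v01 = luts[i0[:, None], j1[None, :], img]
    v10 = luts[i1[:, None], j0[None, :], img]
    v11 = luts[i1[:, None], j1[None, :], img]
    out = (
        (1 - wy) * ((1 - wx) * v00 + wx * v01)
        + wy * ((1 - wx) * v10 + wx * v11)
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
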