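"""Tile stitching: nominal grid placement, overlap-strip refinement by
normalised cross-correlation, and linear-feather blending."""

from __future__ import annotations

import logging
import warnings

import numpy as np
from skimage.registration import phase_cross_correlation

from mpskit.errors import InputError
from mpskit.imaging.types import SlideMosaic, Tile

log = logging.getLogger(__name__)


def stitch_tiles(
    tiles: list[Tile],
    overlap_frac: float,
    refine: bool = True,
    search_frac: float = 0.1,
    pixel_size_um: float = 1.0,
) -> SlideMosaic:
    """Stitch a complete rectangular grid of single-channel tiles.

    Offsets start at the nominal grid positions and, when ``refine`` is on,
    are corrected by cross-correlating each tile's overlap strip against its
    left/top neighbour; corrections beyond ``search_frac`` of the tile size
    fall back to nominal with a warning, as does refinement with zero
    overlap.  Overlapping pixels are blended by linear feathering.
    """
    if not tiles:
        raise InputError("no tiles supplied")
    channels = {t.channel for t in tiles}
    if len(channels) != 1:
        raise InputError(f"tiles span multiple channels: {sorted(channels)}")
    shape = tiles[0].pixels.shape
    if any(t.pixels.shape != shape for t in tiles):
        raise InputError("all tiles must share one shape")

    by_pos = {t.grid_pos: t for t in tiles}
    rows = max(p[0] for p in by_pos) + 1
    cols = max(p[1] for p in by_pos) + 1
    missing = [(r, c) for r in range(rows) for c in range(cols) if (r, c) not in by_pos]
    if missing:
        raise InputError(f"incomplete tile grid; missing cells: {missing}")

    tile_h, tile_w = shape
    stride_r = int(round(tile_h * (1.0 - overlap_frac)))
    stride_c = int(round(tile_w * (1.0 - overlap_frac)))
    ov_r, ov_c = tile_h - stride_r, tile_w - stride_c

    if refine and (ov_r <= 0 or ov_c <= 0):
        warnings.warn(
            "zero overlap: refinement disabled, using nominal offsets", stacklevel=2
        )
        refine = False

    max_shift = max(1, int(round(search_frac * max(tile_h, tile_w))))
    offsets: dict[tuple[int, int], tuple[int, int]] = {(0, 0): (0, 0)}
    for r in range(rows):
        for c in range(cols):
            if (r, c) == (0, 0):
                continue
            candidates = []
            if c > 0:
                left = by_pos[(r, c - 1)]
                base = offsets[(r, c - 1)]
                shift = (0, 0)
                if refine:
                    shift = _strip_shift(
                        left.pixels[:, -ov_c:], by_pos[(r, c)].pixels[:, :ov_c], max_shift
                    )
                candidates.append((base[0] + shift[0], base[1] + stride_c + shift[1]))
            if r > 0:
                top = by_pos[(r - 1, c)]
                base = offsets[(r - 1, c)]
                shift = (0, 0)
                if refine:
                    shift = _strip_shift(
                        top.pixels[-ov_r:, :], by_pos[(r, c)].pixels[:ov_r, :], max_shift
                    )
                candidates.append((base[0] + stride_r + shift[0], base[1] + shift[1]))
            off = tuple(int(round(np.mean(axis))) for axis in zip(*candidates))
            offsets[(r, c)] = off  # type: ignore[assignment]

    min_r = min(o[0] for o in offsets.values())
    min_c = min(o[1] for o in offsets.values())
    offsets = {k: (v[0] - min_r, v[1] - min_c) for k, v in offsets.items()}
    out_h = max(o[0] for o in offsets.values()) + tile_h
    out_w = max(o[1] for o in offsets.values()) + tile_w

    acc = np.zeros((out_h, out_w), dtype=np.float64)
    wacc = np.zeros((out_h, out_w), dtype=np.float64)
    feather = _feather_weights(tile_h, tile_w, max(ov_r, 1), max(ov_c, 1))
    ordered_offsets = []
    for t in tiles:
        orow, ocol = offsets[t.grid_pos]
        acc[orow : orow + tile_h, ocol : ocol + tile_w] += t.pixels * feather
        wacc[orow : orow + tile_h, ocol : ocol + tile_w] += feather
        ordered_offsets.append((orow, ocol))

    mosaic = np.where(wacc > 0, acc / np.maximum(wacc, 1e-12), 0.0).astype(np.float32)
    log.info("stitched %d tiles into %dx%d mosaic", len(tiles), out_h, out_w)
    return SlideMosaic(pixels=mosaic, tile_offsets=ordered_offsets, pixel_size_um=pixel_size_um)


def _strip_shift(
    ref_strip: np.ndarray, mov_strip: np.ndarray, max_shift: int
) -> tuple[int, int]:
    """Residual (row, col) shift of ``mov_strip`` relative to ``ref_strip``.

    Phase correlation on the nominally aligned strips; constant strips or
    shifts beyond the search window fall back to (0, 0)."""
    if ref_strip.std() < 1e-9 or mov_strip.std() < 1e-9:
        return (0, 0)
    shift, _, _ = phase_cross_correlation(ref_strip, mov_strip, normalization="phase")
    dr, dc = int(round(shift[0])), int(round(shift[1]))
    if abs(dr) > max_shift or abs(dc) > max_shift:
        warnings.warn(
            f"refined shift {(dr, dc)} outside search window; using nominal offset",
            stacklevel=3,
        )
        return (0, 0)
    return (dr, dc)


def _feather_weights(h: int, w: int, ov_r: int, ov_c: int) -> np.ndarray:
    """Separable linear ramp from the tile border over the overlap width."""
    ramp_r = np.minimum(1.0, (np.minimum(np.arange(h), np.arange(h)[::-1]) + 1) / (ov_r + 1))
    ramp_c = np.minimum(1.0, (np.minimum(np.arange(w), np.arange(w)[::-1]) + 1) / (ov_c + 1))
    return np.outer(ramp_r, ramp_c)
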