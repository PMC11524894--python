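"""Tile-based inference harness.

Whole-slide rasters are processed at a fixed working resolution of
1.0 micron/pixel (roughly 10x magnification) in non-overlapping tiles of
512 px.  A pluggable segmenter is applied per tile and the tile outputs
are stitched verbatim into a whole-slide label mask — no post-filtering,
smoothing or boundary blending of any kind, so for any deterministic
per-pixel segmenter the tiled result is bit-identical to applying the
segmenter to the whole raster at once.

Trained neural-network segmenters are outside this package; two
deterministic stand-ins (:func:`identity_segmenter`,
:func:`make_toy_segmenter`) exercise the harness end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import SegmenterContractError, ShapeError
from .masks import ClassLegend, TissueMask

DEFAULT_TILE_SIZE = 512
DEFAULT_TARGET_MPP = 1.0

#: A segmenter maps a (h, w[, c]) tile to an (h, w) class-id raster.
Segmenter = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class Tile:
    row: int
    col: int
    height: int
    width: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row, self.row + self.height),
                slice(self.col, self.col + self.width))


@dataclass(frozen=True)
class TileGrid:
    height: int
    width: int
    tile_size_px: int
    tiles: tuple[Tile, ...]


def plan_grid(height: int, width: int, tile_size: int = DEFAULT_TILE_SIZE) -> TileGrid:
    """Plan a non-overlapping exact-cover tiling of a raster.

    Edge tiles may be smaller than ``tile_size`` (ragged edges, no
    padding): the tiles partition the full extent exactly once.
    """
    if height <= 0 or width <= 0:
        raise ValueError(f"raster dimensions must be positive, got {height}x{width}")
    if tile_size <= 0:
        raise ValueError(f"tile_size must be positive, got {tile_size}")
    tiles = []
    for r in range(0, height, tile_size):
        h = min(tile_size, height - r)
        for c in range(0, width, tile_size):
            w = min(tile_size, width - c)
            tiles.append(Tile(r, c, h, w))
    return TileGrid(height=height, width=width, tile_size_px=tile_size,
                    tiles=tuple(tiles))


def run_inference(
    image_or_mask: np.ndarray,
    segmenter: Segmenter,
    grid: TileGrid,
    legend: ClassLegend,
    origin_slide: str | None = None,
) -> TissueMask:
    """Apply a segmenter tile-by-tile and stitch a whole-slide mask.

    Tile outputs are placed verbatim at their tile location.  Each output
    must match its input tile's height/width and contain only class ids
    of ``legend``; a violation raises :class:`SegmenterContractError`
    identifying the offending tile.
    """
    arr = np.asarray(image_or_mask)
    if arr.shape[:2] != (grid.height, grid.width):
        raise ShapeError(
            f"input extent {arr.shape[:2]} != grid extent "
            f"({grid.height}, {grid.width})"
        )
    out = np.zeros((grid.height, grid.width), dtype=np.int64)
    for tile in grid.tiles:
        pred = np.asarray(segmenter(arr[tile.slices]))
        if pred.shape != (tile.height, tile.width):
            raise SegmenterContractError(
                f"tile at ({tile.row}, {tile.col}): segmenter returned shape "
                f"{pred.shape}, expected ({tile.height}, {tile.width})"
            )
        if not np.issubdtype(pred.dtype, np.integer):
            raise SegmenterContractError(
                f"tile at ({tile.row}, {tile.col}): segmenter returned "
                f"non-integer dtype {pred.dtype}"
            )
        if pred.size and (pred.min() < 0 or pred.max() >= legend.n_classes):
            raise SegmenterContractError(
                f"tile at ({tile.row}, {tile.col}): output ids outside legend "
                f"range 0..{legend.n_classes - 1}"
            )
        out[tile.slices] = pred
    return TissueMask(labels=out, legend=legend, origin_slide=origin_slide)


def rescale_to_target_mpp(
    raster: np.ndarray, source_mpp: float, target_mpp: float
) -> np.ndarray:
    """Nearest-neighbor rescale of a label raster between resolutions.

    The linear scale factor is ``source_mpp / target_mpp``.  Nearest
    neighbor is the only admissible interpolation for class-id rasters:
    any averaging would fabricate classes absent from the source.
    Returns the input unchanged when the resolutions already agree.
    """
    if source_mpp <= 0 or target_mpp <= 0:
        raise ValueError(
            f"mpp values must be positive, got {source_mpp} -> {target_mpp}"
        )
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ShapeError(f"expected 2-D raster, got shape {raster.shape}")
    if source_mpp == target_mpp:
        return raster
    scale = source_mpp / target_mpp
    h, w = raster.shape
    out_h = max(1, int(round(h * scale)))
    out_w = max(1, int(round(w * scale)))
    # center-of-pixel mapping: output pixel i samples source pixel
    # floor((i + 0.5) / scale)
    rows = np.minimum(((np.arange(out_h) + 0.5) / scale).astype(np.int64), h - 1)
    cols = np.minimum(((np.arange(out_w) + 0.5) / scale).astype(np.int64), w - 1)
    return raster[np.ix_(rows, cols)]


# -- stand-in segmenters -------------------------------------------------


def identity_segmenter(tile: np.ndarray) -> np.ndarray:
    """Pass-through stand-in: the input tile is already a label raster."""
    tile = np.asarray(tile)
    if tile.ndim != 2:
        raise SegmenterContractError(
            "identity segmenter requires a single-channel label tile"
        )
    return tile


def make_toy_segmenter(legend: ClassLegend) -> Segmenter:
    """Deterministic intensity-threshold stand-in segmenter.

    Bins each pixel's intensity (mean over channels for RGB input) into
    the legend's class ids.  Purely per-pixel, hence exactly tileable.
    """
    n = legend.n_classes

    def toy(tile: np.ndarray) -> np.ndarray:
        tile = np.asarray(tile)
        if tile.ndim == 3:
            tile = tile.mean(axis=2)
        intensity = np.clip(tile.astype(np.float64), 0, 255)
        return np.minimum((intensity * n / 256.0).astype(np.int64), n - 1)

    return toy
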