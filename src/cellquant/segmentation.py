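"""Tiled Ridler-Calvard segmentation of transmitted-light micrographs.

The image is cut into a grid of tiles (36 by default, as a 6x6 grid) and
each tile is thresholded independently, so that local background shading
-- shadows cast by an uneven culture-chamber surface -- receives a local
threshold.  Per tile, a Ridler-Calvard (ISODATA) threshold is computed,
a Gaussian filter (sigma 6 px by default) is applied, and the threshold
is then employed on the smoothed tile; dark pixels are cells.  The
per-tile binary decisions are stitched back into a full-image cell mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ParameterError

POLARITIES = ("dark_cells", "bright_cells")
THRESHOLD_SOURCES = ("raw_tile", "smoothed_tile")


@dataclass(frozen=True)
class SegmentationParams:
    """Tiling grid, smoothing and threshold settings.

    Parameters
    ----------
    grid_rows, grid_cols : int
        Tile grid; the default 6 x 6 yields the standard 36 tiles.
    sigma_px : float
        Gaussian smoothing sigma in pixels (default 6).
    polarity : {"dark_cells", "bright_cells"}
        Whether cells are darker or brighter than the background.
        Transmitted-light acquisition with slight defocus makes cells
        constantly darker than the background, hence the default.
    threshold_on : {"raw_tile", "smoothed_tile"}
        Which version of the tile feeds the threshold computation; the
        threshold is always *applied* to the smoothed tile.
    max_iter, tol : int, float
        Stopping rule for the ISODATA iteration (tol in intensity units).
    min_contrast : float
        Minimum separation between the two converged intensity classes
        for a tile to be considered to contain cells at all; tiles below
        it (blank background, pure noise/shading) yield no foreground.
    """

    grid_rows: int = 6
    grid_cols: int = 6
    sigma_px: float = 6.0
    polarity: str = "dark_cells"
    threshold_on: str = "raw_tile"
    max_iter: int = 100
    tol: float = 0.5
    min_contrast: float = 20.0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ParameterError("grid_rows and grid_cols must be >= 1")
        if self.sigma_px < 0:
            raise ParameterError("sigma_px must be >= 0")
        if self.tol <= 0:
            raise ParameterError("tol must be > 0")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.polarity not in POLARITIES:
            raise ParameterError(f"polarity must be one of {POLARITIES}")
        if self.threshold_on not in THRESHOLD_SOURCES:
            raise ParameterError(f"threshold_on must be one of {THRESHOLD_SOURCES}")

    @property
    def n_tiles(self) -> int:
        return self.grid_rows * self.grid_cols

    def with_grid(self, grid_rows: int, grid_cols: int) -> "SegmentationParams":
        return replace(self, grid_rows=grid_rows, grid_cols=grid_cols)


GLOBAL_THRESHOLD = SegmentationParams(grid_rows=1, grid_cols=1)


@dataclass(frozen=True)
class TileGrid:
    """Exact partition of an image into a grid of tiles."""

    row_bounds: tuple[int, ...]
    col_bounds: tuple[int, ...]

    def tiles(self):
        """Yield (row_start, row_stop, col_start, col_stop) per tile."""
        for r0, r1 in zip(self.row_bounds[:-1], self.row_bounds[1:]):
            for c0, c1 in zip(self.col_bounds[:-1], self.col_bounds[1:]):
                yield r0, r1, c0, c1


def _axis_bounds(extent: int, n: int) -> tuple[int, ...]:
    base, rem = divmod(extent, n)
    sizes = [base + 1] * rem + [base] * (n - rem)
    return tuple(np.concatenate([[0], np.cumsum(sizes)]).tolist())


def make_tile_grid(
    height_px: int, width_px: int, grid_rows: int, grid_cols: int
) -> TileGrid:
    """Partition ``height_px x width_px`` into a grid of near-equal tiles.

    Tile sizes along each axis differ by at most one pixel; the remainder
    is spread over the first tiles.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ParameterError("grid must have at least one row and one column")
    if grid_rows > height_px or grid_cols > width_px:
        raise ParameterError(
            f"grid {grid_rows}x{grid_cols} exceeds image {height_px}x{width_px}"
        )
    return TileGrid(
        row_bounds=_axis_bounds(height_px, grid_rows),
        col_bounds=_axis_bounds(width_px, grid_cols),
    )


def ridler_calvard_threshold(
    tile: np.ndarray, max_iter: int = 100, tol: float = 0.5
) -> float:
    """Ridler-Calvard (ISODATA) threshold of an intensity tile.

    Starting from the global mean, iterate
    ``T <- (mean of intensities <= T + mean of intensities > T) / 2``
    until the update falls below ``tol`` or ``max_iter`` is reached.  If
    either class becomes empty the current value is already a fixed
    point and is returned unchanged (e.g. a uniform tile returns its
    constant intensity).
    """
    x = np.asarray(tile, dtype=np.float64).ravel()
    if x.size == 0:
        raise ParameterError("cannot threshold an empty tile")
    t = float(x.mean())
    for _ in range(max_iter):
        low = x[x <= t]
        high = x[x > t]
        if low.size == 0 or high.size == 0:
            break
        t_new = 0.5 * (low.mean() + high.mean())
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return float(t)


def gaussian_smooth(tile: np.ndarray, sigma_px: float) -> np.ndarray:
    """Isotropic Gaussian smoothing, reflect padding, kernel truncated at 4 sigma."""
    if sigma_px < 0:
        raise ParameterError("sigma_px must be >= 0")
    tile = np.asarray(tile, dtype=np.float64)
    if sigma_px == 0:
        return tile.copy()
    return ndimage.gaussian_filter(tile, sigma=sigma_px, mode="reflect", truncate=4.0)


def segment_tile(tile: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binary cell mask of a single tile.

    A tile whose intensity range is below ``tol``, or whose converged
    ISODATA classes are separated by less than ``min_contrast``, is
    near-uniform -- no cells distinguishable -- and yields an
    all-background mask.  Otherwise the threshold (computed on the raw
    or smoothed tile per ``params.threshold_on``) is applied to the
    smoothed tile with a strict comparison: pixels exactly at the
    threshold are background.
    """
    tile = np.asarray(tile, dtype=np.float64)
    if tile.size == 0:
        raise ParameterError("cannot segment an empty tile")
    if float(tile.max() - tile.min()) < params.tol:
        return np.zeros(tile.shape, dtype=bool)
    smoothed = gaussian_smooth(tile, params.sigma_px)
    ref = tile if params.threshold_on == "raw_tile" else smoothed
    t = ridler_calvard_threshold(ref, params.max_iter, params.tol)
    low = ref[ref <= t]
    high = ref[ref > t]
    if low.size == 0 or high.size == 0:
        return np.zeros(tile.shape, dtype=bool)
    if float(high.mean() - low.mean()) < params.min_contrast:
        return np.zeros(tile.shape, dtype=bool)
    if params.polarity == "dark_cells":
        return smoothed < t
    return smoothed > t


def segment_image(
    image: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> np.ndarray:
    """Tile the image, segment each tile independently, stitch the masks.

    Deterministic for fixed input and parameters.  A 1x1 grid reproduces
    classic global thresholding exactly.
    """
    image = np.asarray(image, dtype=np.float64)
    grid = make_tile_grid(image.shape[0], image.shape[1], params.grid_rows, params.grid_cols)
    mask = np.zeros(image.shape, dtype=bool)
    for r0, r1, c0, c1 in grid.tiles():
        mask[r0:r1, c0:c1] = segment_tile(image[r0:r1, c0:c1], params)
    return mask
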