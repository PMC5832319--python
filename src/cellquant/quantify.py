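"""Area-fraction, cell-size and cell-count measurements on binary masks.

The cell-covered fraction of the field of view (confluence) is the
pipeline's primary readout: foreground pixels are counted and compared
to the image's total pixel count.  With a pixels-per-unit calibration
the covered area is also expressed in physical units (mm^2 or any other
requested unit).  Connected-component analysis yields a mean cell
footprint from which a cell count is estimated — confluent clusters
merge into single components, so the count comes from total foreground
divided by mean component area rather than from counting components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage

from .errors import NoCellsError, ParameterError

# 8-connectivity: diagonal contacts join blurred cell fragments.
_STRUCTURE_8 = np.ones((3, 3), dtype=int)

DEFAULT_MIN_AREA_PX = 9


@dataclass(frozen=True)
class CalibrationInfo:
    """Spatial calibration: pixels per physical unit of length."""

    pixels_per_unit: float
    unit_name: str = "mm"

    def __post_init__(self) -> None:
        if self.pixels_per_unit <= 0:
            raise ParameterError("pixels_per_unit must be > 0")


@dataclass(frozen=True)
class AreaResult:
    """Measurements derived from one binary cell mask."""

    foreground_px: int
    total_px: int
    area_percent: float
    physical_area: Optional[float] = None
    unit_name: Optional[str] = None
    mean_cell_area_px: Optional[float] = None
    equivalent_diameter_px: Optional[float] = None
    estimated_cell_count: Optional[float] = None


class MeanCellSize(NamedTuple):
    mean_area_px: float
    equivalent_diameter_px: float


def area_fraction(mask: np.ndarray) -> AreaResult:
    """Exact foreground pixel count and percent coverage of a mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ParameterError("mask is empty")
    fg = int(mask.sum())
    total = int(mask.size)
    return AreaResult(
        foreground_px=fg, total_px=total, area_percent=100.0 * fg / total
    )


def to_physical_area(foreground_px: int, calibration: CalibrationInfo) -> float:
    """Convert a pixel count to area in ``unit_name`` squared."""
    if foreground_px < 0:
        raise ParameterError("foreground_px must be >= 0")
    return foreground_px / calibration.pixels_per_unit**2


def label_components(
    mask: np.ndarray, min_area_px: int = DEFAULT_MIN_AREA_PX
) -> np.ndarray:
    """Sizes of 8-connected foreground regions, noise specks removed.

    Regions smaller than ``min_area_px`` are discarded (set it to 0 to
    keep everything).  Returns an array of pixel counts, one per
    surviving region; empty for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    if n == 0:
        return np.array([], dtype=np.int64)
    sizes = np.bincount(labels.ravel())[1:]
    return sizes[sizes >= min_area_px].astype(np.int64)


def estimate_mean_cell_size(region_sizes) -> MeanCellSize:
    """Mean region area in pixels and the equivalent circular diameter.

    The equivalent diameter ``2 * sqrt(mean / pi)`` serves as the mean
    cell height/size proxy.  Raises :class:`NoCellsError` on an empty
    region list.
    """
    sizes = np.asarray(region_sizes, dtype=np.float64)
    if sizes.size == 0:
        raise NoCellsError("no cell regions found")
    mean = float(sizes.mean())
    return MeanCellSize(mean, 2.0 * math.sqrt(mean / math.pi))


def estimate_cell_count(foreground_px: int, mean_cell_area_px: float) -> float:
    """Cell count as total foreground divided by the mean cell footprint."""
    if mean_cell_area_px <= 0:
        raise ParameterError("mean_cell_area_px must be > 0")
    if foreground_px < 0:
        raise ParameterError("foreground_px must be >= 0")
    return foreground_px / mean_cell_area_px


def measure_mask(
    mask: np.ndarray,
    calibration: Optional[CalibrationInfo] = None,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> AreaResult:
    """Full measurement of one mask: coverage, physical area, size, count."""
    base = area_fraction(mask)
    physical = unit = None
    if calibration is not None:
        physical = to_physical_area(base.foreground_px, calibration)
        unit = calibration.unit_name
    sizes = label_components(mask, min_area_px=min_area_px)
    if sizes.size:
        mean_size = estimate_mean_cell_size(sizes)
        count = estimate_cell_count(base.foreground_px, mean_size.mean_area_px)
        return AreaResult(
            foreground_px=base.foreground_px,
            total_px=base.total_px,
            area_percent=base.area_percent,
            physical_area=physical,
            unit_name=unit,
            mean_cell_area_px=mean_size.mean_area_px,
            equivalent_diameter_px=mean_size.equivalent_diameter_px,
            estimated_cell_count=count,
        )
    return AreaResult(
        foreground_px=base.foreground_px,
        total_px=base.total_px,
        area_percent=base.area_percent,
        physical_area=physical,
        unit_name=unit,
        estimated_cell_count=0.0 if base.foreground_px == 0 else None,
    )
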