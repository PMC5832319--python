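"""Reading and writing micrographs, masks and batch manifests.

Images are handled as plain 2-D float64 arrays with intensities on the
8-bit scale [0, 255]; binary masks are 2-D boolean arrays with ``True``
marking cell pixels.  Mask files on disk follow the black-cells /
white-background convention (cell pixels 0, background 255).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import BoundsError, FormatError, InputError, ParameterError

# Rec. 601 luminance weights for RGB -> gray conversion.
_REC601 = np.array([0.299, 0.587, 0.114])

MANIFEST_COLUMNS = ["image_path", "condition", "timepoint_days", "replicate_id"]


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular crop region, half-open pixel intervals."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def validate(self, height_px: int, width_px: int) -> None:
        if not (0 <= self.row_start < self.row_stop <= height_px):
            raise BoundsError(
                f"row interval [{self.row_start}, {self.row_stop}) invalid for "
                f"image height {height_px}"
            )
        if not (0 <= self.col_start < self.col_stop <= width_px):
            raise BoundsError(
                f"col interval [{self.col_start}, {self.col_stop}) invalid for "
                f"image width {width_px}"
            )


def load_grayscale(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/TIFF/JPEG raster as a 2-D float64 array in [0, 255].

    RGB(A) inputs are converted with the Rec. 601 luminance weighting
    (0.299 R + 0.587 G + 0.114 B, alpha discarded); 16-bit inputs are
    linearly rescaled by the full dtype range so that thresholds remain
    comparable across a batch.
    """
    if not os.path.isfile(path):
        raise InputError(f"image file not found: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # corrupted / non-raster file
        raise FormatError(f"cannot read raster from {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.size == 0:
        raise FormatError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., :3].astype(np.float64) @ _REC601
        elif arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            raise FormatError(f"unsupported channel count {arr.shape[2]}: {path}")
    elif arr.ndim != 2:
        raise FormatError(f"expected a 2-D raster, got shape {arr.shape}: {path}")
    arr = np.asarray(arr, dtype=np.float64)
    if raw.dtype == np.uint16:
        arr = arr * (255.0 / 65535.0)
    elif raw.dtype == np.int32 or raw.dtype == np.uint32:
        arr = arr * (255.0 / np.iinfo(raw.dtype).max)
    return np.clip(arr, 0.0, 255.0)


def crop(image: np.ndarray, roi: RegionOfInterest) -> np.ndarray:
    """Copy the rectangular region ``roi`` out of ``image``."""
    image = np.asarray(image)
    roi.validate(image.shape[0], image.shape[1])
    return image[roi.row_start : roi.row_stop, roi.col_start : roi.col_stop].copy()


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean cell mask as an 8-bit PNG, cells black (0) on white (255)."""
    mask = np.asarray(mask, dtype=bool)
    out = np.where(mask, 0, 255).astype(np.uint8)
    try:
        iio.imwrite(path, out)
    except OSError as exc:
        raise InputError(f"cannot write mask to {path}: {exc}") from exc


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask PNG back to a boolean array (True = cell = dark pixel)."""
    arr = load_grayscale(path)
    return arr < 128.0


def load_manifest(path: str | os.PathLike, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a batch manifest CSV.

    Expected header: ``image_path,condition,timepoint_days,replicate_id``.
    Relative image paths are resolved against the manifest's directory.
    """
    if not os.path.isfile(path):
        raise InputError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"condition": str, "replicate_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} lacks required columns {missing}")
    if df["image_path"].duplicated().any():
        dup = df.loc[df["image_path"].duplicated(), "image_path"].iloc[0]
        raise ParameterError(f"duplicate manifest entry: {dup}")
    if (df["timepoint_days"] < 0).any():
        raise ParameterError("timepoint_days must be non-negative")
    base = os.path.dirname(os.path.abspath(path))
    df = df.copy()
    df["image_path"] = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in df["image_path"]
    ]
    if check_files:
        absent = [p for p in df["image_path"] if not os.path.isfile(p)]
        if absent:
            raise InputError(f"manifest references missing files, e.g. {absent[0]}")
    return df


def write_manifest(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)
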