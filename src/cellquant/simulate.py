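"""Seeded generator of transmitted-light-like micrographs with ground truth.

The generator emulates the acquisition regime the pipeline is built for:
slightly defocused cells that are constantly darker than the background,
an uneven chamber surface whose irregularities cast shadows (a lateral
illumination gradient plus smooth dark shading blobs), optional dark
chamber-boundary lines, and a mixture of fusiform (spindle, axis ratio
3-6) and rounded (axis ratio 1-1.3) cell footprints.  Cells are rendered
as ellipses at a constant negative intensity offset, blurred to imitate
defocus, composited over the background and dosed with pixel noise; the
ground-truth mask records the exact pre-blur ellipse geometry, so every
downstream measurement can be scored against a known answer.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .io import MANIFEST_COLUMNS

DEFAULT_C0_PERCENT = 2.0
DEFAULT_CMAX_PERCENT = 60.0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic micrograph.

    Intensity fields are on the 8-bit scale.  ``cell_intensity_offset``
    is negative because defocused transmitted-light cells are darker
    than the background; ``gradient_amplitude`` is the total intensity
    swing of a linear left-to-right background ramp; shading blobs are
    smooth dark patches standing in for shadows of the uneven chamber
    surface.  ``max_overlap_fraction`` caps how much of a new cell may
    land on already-placed cells (1.0 disables rejection entirely, as in
    a confluent culture); ``min_separation_px`` pads the overlap test so
    accepted cells keep a clear gap, which keeps them countable.
    """

    height_px: int = 600
    width_px: int = 600
    background_level: float = 200.0
    gradient_amplitude: float = 60.0
    n_shading_blobs: int = 3
    shading_depth: float = 20.0
    shading_sigma_px: float = 90.0
    cell_count: int = 120
    mean_cell_area_px: float = 600.0
    cell_area_jitter: float = 0.3
    fusiform_fraction: float = 0.5
    cell_intensity_offset: float = -50.0
    cell_blur_sigma_px: float = 2.0
    noise_sd: float = 3.0
    chamber_border: bool = False
    max_overlap_fraction: float = 0.05
    min_separation_px: float = 0.0
    max_attempts_per_cell: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ParameterError("scene dimensions must be positive")
        if self.cell_count < 0:
            raise ParameterError("cell_count must be >= 0")
        if not 0.0 <= self.fusiform_fraction <= 1.0:
            raise ParameterError("fusiform_fraction must lie in [0, 1]")
        if self.mean_cell_area_px <= 0:
            raise ParameterError("mean_cell_area_px must be > 0")
        if not 0.0 <= self.max_overlap_fraction <= 1.0:
            raise ParameterError("max_overlap_fraction must lie in [0, 1]")
        lo = self.background_level + self.cell_intensity_offset
        if not (0.0 <= lo and self.background_level <= 255.0):
            raise ParameterError(
                "background_level + cell_intensity_offset must stay within [0, 255]"
            )


@dataclass(frozen=True)
class SyntheticScene:
    """A generated micrograph with its exact ground truth."""

    image: np.ndarray
    truth_mask: np.ndarray
    true_cell_count: int
    true_coverage_percent: float
    spec: SceneSpec


def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Boolean raster of an ellipse (semi-axes a >= b, rotated by theta)."""
    h, w = shape
    r0 = max(0, int(math.floor(cy - a - 1)))
    r1 = min(h, int(math.ceil(cy + a + 2)))
    c0 = max(0, int(math.floor(cx - a - 1)))
    c1 = min(w, int(math.ceil(cx + a + 2)))
    out = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return out
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    out[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def _sample_cell(rng: np.random.Generator, spec: SceneSpec):
    area = spec.mean_cell_area_px * rng.uniform(
        1.0 - spec.cell_area_jitter, 1.0 + spec.cell_area_jitter
    )
    if rng.uniform() < spec.fusiform_fraction:
        ratio = rng.uniform(3.0, 6.0)
    else:
        ratio = rng.uniform(1.0, 1.3)
    a = math.sqrt(area * ratio / math.pi)
    b = a / ratio
    cy = rng.uniform(0, spec.height_px)
    cx = rng.uniform(0, spec.width_px)
    theta = rng.uniform(0, math.pi)
    return cy, cx, a, b, theta


def _background(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    ramp = np.linspace(
        -spec.gradient_amplitude / 2.0, spec.gradient_amplitude / 2.0, w
    )
    bg = np.full((h, w), spec.background_level, dtype=np.float64) + ramp[None, :]
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_shading_blobs):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        depth = spec.shading_depth * rng.uniform(0.5, 1.0)
        sig = spec.shading_sigma_px * rng.uniform(0.7, 1.3)
        bg -= depth * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sig**2))
    if spec.chamber_border:
        t = max(2, h // 200)
        inset = max(4, h // 120)
        dark = spec.background_level + spec.cell_intensity_offset
        bg[inset : inset + t, :] = dark
        bg[h - inset - t : h - inset, :] = dark
        bg[:, inset : inset + t] = dark
        bg[:, w - inset - t : w - inset] = dark
    return bg


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one synthetic micrograph; bit-identical for a fixed seed.

    Cell placement is rejection-sampled: a candidate ellipse is accepted
    only if the fraction of its pixels already covered by earlier cells
    does not exceed ``max_overlap_fraction`` (with ``min_separation_px``
    of padding around it in the test).  When packing cannot satisfy the
    request, a :class:`GenerationError` names the limiting parameter.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)
    truth = np.zeros(shape, dtype=bool)
    placed = 0
    for _ in range(spec.cell_count):
        accepted = False
        for _attempt in range(spec.max_attempts_per_cell):
            cy, cx, a, b, theta = _sample_cell(rng, spec)
            m = _ellipse_mask(shape, cy, cx, a, b, theta)
            n_px = int(m.sum())
            if n_px == 0:
                continue
            if spec.max_overlap_fraction >= 1.0:
                accepted = True
                break
            pad = spec.min_separation_px
            test = (
                m
                if pad <= 0
                else _ellipse_mask(shape, cy, cx, a + pad, b + pad, theta)
            )
            overlap = int((test & truth).sum()) / int(test.sum())
            if overlap <= spec.max_overlap_fraction:
                accepted = True
                break
        if not accepted:
            raise GenerationError(
                f"could not place cell {placed + 1}/{spec.cell_count} within "
                f"{spec.max_attempts_per_cell} attempts; max_overlap_fraction="
                f"{spec.max_overlap_fraction} is the limiting parameter"
            )
        truth |= m
        placed += 1

    bg = _background(rng, spec)
    offset_field = np.where(truth, spec.cell_intensity_offset, 0.0)
    if spec.cell_blur_sigma_px > 0:
        from scipy import ndimage

        offset_field = ndimage.gaussian_filter(
            offset_field, sigma=spec.cell_blur_sigma_px, mode="reflect"
        )
    img = bg + offset_field
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(img, 0.0, 255.0)
    coverage = 100.0 * float(truth.sum()) / truth.size
    return SyntheticScene(
        image=img,
        truth_mask=truth,
        true_cell_count=placed,
        true_coverage_percent=coverage,
        spec=spec,
    )


def cell_count_for_coverage(spec: SceneSpec, coverage_percent: float) -> int:
    """Cell count expected to produce ``coverage_percent`` under ``spec``.

    With unrestricted overlap, random ellipse unions follow the Boolean
    model: coverage = 1 - exp(-n A / total), inverted here.  With an
    overlap cap the union is nearly additive and the naive count is
    corrected by the mean permitted overlap.
    """
    if not 0.0 <= coverage_percent < 100.0:
        raise ParameterError("coverage_percent must lie in [0, 100)")
    c = coverage_percent / 100.0
    total = spec.height_px * spec.width_px
    if c == 0.0:
        return 0
    if spec.max_overlap_fraction >= 1.0:
        n = -math.log(1.0 - c) * total / spec.mean_cell_area_px
    else:
        n = c * total / (spec.mean_cell_area_px * (1.0 - spec.max_overlap_fraction / 2.0))
    return max(1, round(n))


def logistic_coverage(
    t_days: float,
    rate_per_day: float,
    c0_percent: float = DEFAULT_C0_PERCENT,
    cmax_percent: float = DEFAULT_CMAX_PERCENT,
) -> float:
    """Logistic confluence curve c(t) = cmax / (1 + ((cmax-c0)/c0) e^(-r t))."""
    if rate_per_day < 0:
        raise ParameterError("growth rate must be >= 0")
    ratio = (cmax_percent - c0_percent) / c0_percent
    return cmax_percent / (1.0 + ratio * math.exp(-rate_per_day * t_days))


def write_scene(scene: SyntheticScene, image_path: str, mask_path: Optional[str] = None) -> None:
    """Write a scene's image (and optionally its truth mask) as 8-bit PNGs."""
    img8 = np.clip(np.rint(scene.image), 0, 255).astype(np.uint8)
    iio.imwrite(image_path, img8)
    if mask_path is not None:
        iio.imwrite(
            mask_path, np.where(scene.truth_mask, 0, 255).astype(np.uint8)
        )


def generate_growth_series(
    conditions: Sequence[tuple[str, float]],
    days: Sequence[float],
    replicates: int,
    out_dir: str,
    base_spec: Optional[SceneSpec] = None,
    seed: int = 0,
    c0_percent: float = DEFAULT_C0_PERCENT,
    cmax_percent: float = DEFAULT_CMAX_PERCENT,
    write_masks: bool = True,
) -> pd.DataFrame:
    """Emulate a growth experiment: one scene per condition x day x replicate.

    ``conditions`` pairs a label (e.g. an FBS percentage) with a
    logistic growth rate per day.  Cell counts are chosen so the true
    coverage follows the logistic curve from ``c0_percent`` towards
    ``cmax_percent``.  Scenes are written as PNGs together with truth
    masks, a manifest CSV and a JSON dump of every scene spec; the whole
    series is deterministic for a fixed seed.  Returns the manifest
    (with a ``true_coverage_percent`` column appended for convenience).
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    if len(conditions) == 0 or len(days) == 0:
        raise ParameterError("need at least one condition and one day")
    for _, rate in conditions:
        if rate < 0:
            raise ParameterError("growth rates must be >= 0")
    base = base_spec or SceneSpec()
    # confluent series: free overlap, Boolean-model count inversion
    base = dataclasses.replace(base, max_overlap_fraction=1.0)
    os.makedirs(out_dir, exist_ok=True)
    img_dir = os.path.join(out_dir, "images")
    mask_dir = os.path.join(out_dir, "masks")
    os.makedirs(img_dir, exist_ok=True)
    if write_masks:
        os.makedirs(mask_dir, exist_ok=True)

    rows = []
    specs_dump = []
    idx = 0
    for label, rate in conditions:
        for day in days:
            cov = logistic_coverage(day, rate, c0_percent, cmax_percent)
            for rep in range(1, replicates + 1):
                scene_seed = int(
                    np.random.SeedSequence([int(seed), idx]).generate_state(1)[0]
                    % (2**31)
                )
                spec = dataclasses.replace(
                    base,
                    cell_count=cell_count_for_coverage(base, cov),
                    seed=scene_seed,
                )
                scene = generate_scene(spec)
                stem = f"{label}_d{day:g}_r{rep}".replace("%", "pct").replace(
                    ".", "p"
                )
                img_path = os.path.join(img_dir, f"{stem}.png")
                mask_path = (
                    os.path.join(mask_dir, f"{stem}_truth.png") if write_masks else None
                )
                write_scene(scene, img_path, mask_path)
                rows.append(
                    {
                        "image_path": img_path,
                        "condition": label,
                        "timepoint_days": float(day),
                        "replicate_id": f"r{rep}",
                        "true_coverage_percent": scene.true_coverage_percent,
                    }
                )
                specs_dump.append(
                    {"image": os.path.basename(img_path), **dataclasses.asdict(spec)}
                )
                idx += 1

    manifest = pd.DataFrame(rows)
    manifest[MANIFEST_COLUMNS + ["true_coverage_percent"]].to_csv(
        os.path.join(out_dir, "manifest.csv"), index=False
    )
    with open(os.path.join(out_dir, "scenes.json"), "w") as fh:
        json.dump(specs_dump, fh, indent=1)
    return manifest
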