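"""Batch processing and growth-curve statistics.

Runs the segmentation pipeline over a manifest of micrographs,
aggregates coverage per condition x timepoint as mean +/- SEM growth
curves, and tests for condition differences with a Kruskal-Wallis
omnibus followed by Dunn's rank-based post-hoc pairwise comparisons
(Bonferroni-adjusted by default, alpha = 0.05).  Classical one-way
ANOVA is available as an alternative omnibus.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from .io import RegionOfInterest, crop, load_grayscale
from .quantify import DEFAULT_MIN_AREA_PX, AreaResult, CalibrationInfo, measure_mask
from .segmentation import SegmentationParams, segment_image

logger = logging.getLogger("cellquant")

ALPHA = 0.05

RESULT_COLUMNS = [
    "image_path",
    "condition",
    "timepoint_days",
    "replicate_id",
    "foreground_px",
    "total_px",
    "area_percent",
    "physical_area",
    "mean_cell_area_px",
    "estimated_cell_count",
]


@dataclass(frozen=True)
class GrowthRecord:
    """Per-image measurement tagged with its experimental coordinates."""

    image_path: str
    condition: str
    timepoint_days: float
    replicate_id: str
    result: AreaResult

    @property
    def area_percent(self) -> float:
        return self.result.area_percent


@dataclass(frozen=True)
class PairwiseComparison:
    """One Dunn post-hoc comparison between two conditions."""

    group_a: str
    group_b: str
    z_statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


def run_batch(
    manifest: pd.DataFrame,
    params: SegmentationParams = SegmentationParams(),
    calibration: Optional[CalibrationInfo] = None,
    roi: Optional[RegionOfInterest] = None,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> list[GrowthRecord]:
    """Segment and measure every manifest row; skip and log failures.

    One unreadable image must not abort a thousand-image batch: failures
    are logged with a per-file diagnostic and omitted from the output,
    which otherwise preserves manifest order.
    """
    if len(manifest) == 0:
        raise ParameterError("manifest is empty")
    records: list[GrowthRecord] = []
    for row in manifest.itertuples(index=False):
        t0 = time.perf_counter()
        try:
            image = load_grayscale(row.image_path)
            if roi is not None:
                image = crop(image, roi)
            mask = segment_image(image, params)
            result = measure_mask(mask, calibration=calibration, min_area_px=min_area_px)
        except Exception as exc:
            logger.warning("skipping %s: %s", row.image_path, exc)
            continue
        logger.info(
            "%s: %.2f%% covered (%.3f s)",
            row.image_path,
            result.area_percent,
            time.perf_counter() - t0,
        )
        records.append(
            GrowthRecord(
                image_path=str(row.image_path),
                condition=str(row.condition),
                timepoint_days=float(row.timepoint_days),
                replicate_id=str(row.replicate_id),
                result=result,
            )
        )
    return records


def records_to_frame(records: Sequence[GrowthRecord]) -> pd.DataFrame:
    """Flatten growth records into the tabular results layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "image_path": r.image_path,
                "condition": r.condition,
                "timepoint_days": r.timepoint_days,
                "replicate_id": r.replicate_id,
                "foreground_px": r.result.foreground_px,
                "total_px": r.result.total_px,
                "area_percent": r.result.area_percent,
                "physical_area": r.result.physical_area,
                "mean_cell_area_px": r.result.mean_cell_area_px,
                "estimated_cell_count": r.result.estimated_cell_count,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def summarize(records) -> pd.DataFrame:
    """Mean +/- SEM of area_percent per (condition, timepoint).

    SEM is the sample standard deviation (ddof 1) over sqrt(n); it is 0
    when all replicates are equal and reported as missing when n = 1.
    Accepts a list of :class:`GrowthRecord` or a results DataFrame.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) == 0:
        raise ParameterError("no records to summarize")
    grouped = df.groupby(["condition", "timepoint_days"], sort=True)["area_percent"]
    out = grouped.agg(
        n="count",
        mean_area_percent="mean",
        sem=lambda v: np.nan if len(v) < 2 else float(np.std(v, ddof=1) / np.sqrt(len(v))),
    ).reset_index()
    return out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank test with tie correction.

    Returns (H, p) with p from the chi-square approximation on k-1
    degrees of freedom.  When every observation is identical the
    statistic is defined as 0 (p = 1).
    """
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ParameterError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F-test (optional omnibus alternative)."""
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    f, p = sps.f_oneway(*[np.asarray(g, dtype=np.float64) for g in groups])
    return float(f), float(p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    adjust: str = "bonferroni",
    alpha: float = ALPHA,
) -> list[PairwiseComparison]:
    """Dunn's rank-based pairwise comparisons following Kruskal-Wallis.

    For each pair (i, j),

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    where Rbar are mean ranks of the pooled sample and the tie term is
    ``T = sum(t^3 - t) / (12 (N - 1))`` over tie groups of size t.
    Two-sided p-values come from the standard normal and are adjusted
    across all k(k-1)/2 comparisons (Bonferroni by default; "sidak" and
    "none" are also available).
    """
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    if adjust not in ("bonferroni", "sidak", "none"):
        raise ParameterError(f"unknown adjustment: {adjust}")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ParameterError("groups must be non-empty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ParameterError("labels must match groups")

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = [
        float(ranks[offsets[i] : offsets[i + 1]].mean()) for i in range(len(arrays))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    raw: list[tuple[int, int, float, float]] = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        denom2 = var_base * (1.0 / sizes[i] + 1.0 / sizes[j])
        if denom2 <= 0:  # all observations tie: no evidence either way
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom2)
        p = float(2.0 * sps.norm.sf(abs(z)))
        raw.append((i, j, float(z), p))

    m = len(raw)
    out = []
    for i, j, z, p in raw:
        if adjust == "bonferroni":
            p_adj = min(1.0, p * m)
        elif adjust == "sidak":
            p_adj = 1.0 - (1.0 - p) ** m
        else:
            p_adj = p
        out.append(
            PairwiseComparison(
                group_a=str(labels[i]),
                group_b=str(labels[j]),
                z_statistic=z,
                p_raw=p,
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[PairwiseComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "z": c.z_statistic,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
                "significant": c.significant,
            }
            for c in comparisons
        ],
        columns=["group_a", "group_b", "z", "p_raw", "p_adjusted", "significant"],
    )


def condition_groups_at(
    results: pd.DataFrame, timepoint_days: Optional[float] = None
) -> tuple[list[str], list[np.ndarray]]:
    """Split area_percent values by condition at one timepoint.

    ``timepoint_days=None`` selects the latest timepoint present.
    """
    if timepoint_days is None:
        timepoint_days = float(results["timepoint_days"].max())
    sel = results[np.isclose(results["timepoint_days"], timepoint_days)]
    labels = sorted(sel["condition"].unique())
    groups = [
        sel.loc[sel["condition"] == lab, "area_percent"].to_numpy() for lab in labels
    ]
    return labels, groups
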