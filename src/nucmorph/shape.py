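"""Per-nucleus shape descriptors and trajectory statistics.

The central quantity is circularity, ``4*pi*area/perimeter**2``: 1 for a
perfect disk and decreasing as the outline becomes irregular.  Because the
formula is quadratic in the perimeter, the perimeter estimator matters: naive
boundary-pixel counting overestimates the length of a digitised circle by
roughly a quarter, which would cap the circularity of a perfect disk near
0.79.  Perimeters here are therefore measured on a sub-pixel polygonal
contour extracted by marching squares at the 0.5 level, so a rasterised disk
scores ~1 as the formula intends.

Trajectory statistics summarise nuclei traced over a handful of timepoints:
for each cell the mean and sample variance (divisor k-1) of perimeter,
circularity and aspect ratio.  A large variance flags a dynamically deforming
nucleus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), bool)

__all__ = [
    "ShapeMetrics",
    "TrajectoryStats",
    "circularity",
    "contour_metrics",
    "trajectory_stats",
    "trajectory_stats_table",
]


@dataclass(frozen=True)
class ShapeMetrics:
    """Shape descriptors of one nucleus, in physical units (um, um^2)."""

    area: float
    perimeter: float
    circularity: float
    aspect_ratio: float
    centroid: tuple[float, float]
    #: circularity before clamping to 1.0 (digitisation can overshoot slightly)
    circularity_raw: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.circularity_raw is None:
            object.__setattr__(self, "circularity_raw", self.circularity)


@dataclass(frozen=True)
class TrajectoryStats:
    cell_id: object
    k: int
    mean_perimeter: float
    var_perimeter: float
    mean_circularity: float
    var_circularity: float
    mean_aspect_ratio: float
    var_aspect_ratio: float


def circularity(area: float, perimeter: float) -> float:
    """``4*pi*area/perimeter**2``, clamped to [0, 1].

    Parameters are in consistent units (the ratio is dimensionless).
    Raises ``ValueError`` for non-positive inputs.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError(
            f"area and perimeter must be positive (got area={area}, perimeter={perimeter})"
        )
    value = 4.0 * np.pi * area / perimeter**2
    return float(min(max(value, 0.0), 1.0))


def _outer_contour(mask: np.ndarray, smooth_sigma: float = 0.85) -> np.ndarray:
    """Sub-pixel outer contour of a binary mask (marching squares, level 0.5).

    The raw marching-squares polygon of a binary image is a staircase that
    overestimates the length of a digitised circle by ~5% (which would cap a
    perfect disk's circularity near 0.91).  The polygon is therefore
    resampled to uniform arc length and its coordinates smoothed along the
    closed curve with a periodic Gaussian (``smooth_sigma`` in pixels of arc
    length): the staircase wavelength (~1-2 px) is suppressed while genuine
    lobes and clefts (tens of px) pass through.  Disks then measure within
    ~1% of their true circumference and strongly lobulated outlines within
    ~2% of their analytic circularity.  Returns an open vertex list.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:  # pragma: no cover - guarded by emptiness check upstream
        raise ValueError("no contour found")

    def shoelace(c: np.ndarray) -> float:
        x, y = c[:, 1], c[:, 0]
        return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

    contour = max(contours, key=shoelace)
    if np.array_equal(contour[0], contour[-1]):
        contour = contour[:-1]
    if smooth_sigma > 0 and len(contour) > 8:
        # canonical start point (farthest vertex from the vertex centroid)
        # so the resampling grid is covariant under translation and rotation
        d = ((contour - contour.mean(axis=0)) ** 2).sum(axis=1)
        contour = np.roll(contour, -int(np.argmax(d)), axis=0)
        # resample to uniform arc length so the filter acts on a geometric
        # scale (px) rather than on the irregular vertex spacing
        step = 0.25
        closed = np.vstack([contour, contour[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        s = np.r_[0.0, np.cumsum(seg)]
        n = max(int(s[-1] / step), 16)
        su = np.linspace(0.0, s[-1], n, endpoint=False)
        y = np.interp(su, s, closed[:, 0])
        x = np.interp(su, s, closed[:, 1])
        sig = smooth_sigma / step
        y = ndi.gaussian_filter1d(y, sig, mode="wrap")
        x = ndi.gaussian_filter1d(x, sig, mode="wrap")
        contour = np.column_stack([y, x])
    return contour


def contour_metrics(mask: np.ndarray, pixel_size: float = 1.0) -> ShapeMetrics:
    """Measure one 8-connected binary region.

    area
        pixel count times ``pixel_size**2``.
    perimeter
        length of the (vertex-smoothed) marching-squares polygon at level
        0.5 times ``pixel_size``; a digitised disk measures within ~1.5%
        of the true circumference.
    aspect_ratio
        major/minor axis of the second-moment-equivalent ellipse (>= 1).
    circularity
        the formula applied to the stored area and perimeter, clamped at 1.0;
        the raw value is kept in ``circularity_raw`` and logged when clamped.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("empty mask")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    _, n_comp = ndi.label(mask, structure=_EIGHT)
    if n_comp != 1:
        raise ValueError(f"mask must contain exactly one 8-connected region (found {n_comp})")

    contour = _outer_contour(mask)
    seg = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    perimeter_px = float(np.sqrt((seg**2).sum(axis=1)).sum())
    area_px = float(mask.sum())

    props = measure.regionprops(mask.astype(np.uint8))[0]
    minor, major = props.axis_minor_length, props.axis_major_length
    aspect = float(major / minor) if minor > 0 else 1.0

    area = area_px * pixel_size**2
    perimeter = perimeter_px * pixel_size
    raw = 4.0 * np.pi * area / perimeter**2
    if raw > 1.0:
        logger.debug("circularity %.4f clamped to 1.0", raw)
    cy, cx = props.centroid
    return ShapeMetrics(
        area=area,
        perimeter=perimeter,
        circularity=float(min(raw, 1.0)),
        aspect_ratio=aspect,
        centroid=(float(cx) * pixel_size, float(cy) * pixel_size),
        circularity_raw=float(raw),
    )


def trajectory_stats(series: Sequence[ShapeMetrics], cell_id: object = None) -> TrajectoryStats:
    """Mean and sample variance (divisor k-1) of shape metrics over time.

    ``series`` is the ordered list of per-timepoint metrics for one cell;
    fewer than two timepoints leave the variance undefined and raise.
    """
    k = len(series)
    if k < 2:
        raise ValueError(f"need at least 2 timepoints for a variance (got {k})")
    per = np.array([m.perimeter for m in series], float)
    circ = np.array([m.circularity for m in series], float)
    ar = np.array([m.aspect_ratio for m in series], float)
    return TrajectoryStats(
        cell_id=cell_id,
        k=k,
        mean_perimeter=float(per.mean()),
        var_perimeter=float(per.var(ddof=1)),
        mean_circularity=float(circ.mean()),
        var_circularity=float(circ.var(ddof=1)),
        mean_aspect_ratio=float(ar.mean()),
        var_aspect_ratio=float(ar.var(ddof=1)),
    )


def trajectory_stats_table(
    table: pd.DataFrame,
    cell_col: str = "cell_id",
    metrics: Iterable[str] = ("perimeter", "circularity", "aspect_ratio"),
) -> pd.DataFrame:
    """Per-cell mean/variance table from a long-format trajectory table.

    Expects one row per (cell, timepoint); returns one row per cell with
    ``mean_<metric>`` and ``var_<metric>`` columns plus ``k``.  Sample
    variance (ddof=1) throughout; cells with fewer than 2 rows raise.
    """
    metrics = list(metrics)
    counts = table.groupby(cell_col).size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"cells with <2 timepoints: {bad}")
    g = table.groupby(cell_col)[metrics]
    out = pd.concat(
        [g.mean().add_prefix("mean_"), g.var(ddof=1).add_prefix("var_")], axis=1
    )
    out["k"] = counts
    return out.reset_index()
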