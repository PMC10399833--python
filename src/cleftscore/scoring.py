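"""Anomaly severity scoring and machine–human agreement evaluation.

The severity score of a masked heatmap ``D`` with region mask ``M`` is

    S = −log( ‖M ⊙ D‖_F / N ),       N = number of mask pixels,

so *higher* heatmap energy gives a *lower* score, aligning the machine scale
with the human 1 (least normal) … 7 (most normal) rating direction. Scores
are optionally affine-rescaled onto the rating interval for plotting; the
rescaling leaves Pearson correlations unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.stats import pearsonr
from skimage.draw import polygon
from skimage.morphology import dilation, disk

from .heatmaps import Heatmap
from .imaging import (BROW_IDX, INNER_MOUTH_IDX, JAW_IDX, LEFT_EYE_IDX,
                      NOSE_IDX, OUTER_MOUTH_IDX, RIGHT_EYE_IDX, LandmarkSet,
                      RegionMask)

__all__ = ["AnomalyScore", "RatingTable", "build_mask", "score",
           "scale_scores", "aggregate_ratings", "pearson"]


@dataclass(frozen=True)
class AnomalyScore:
    """Masked heatmap energy and its negative-log severity score."""

    raw_energy: float
    score: float
    mask_kind: str
    method: str
    ycbcr_applied: bool = False
    erosion_applied: bool = False
    scaled_score: float | None = None
    perfectly_normal: bool = False


class RatingTable:
    """Per-image human ratings on the 1–7 scale (long format)."""

    COLUMNS = ("image_id", "rater_id", "rating")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"rating table missing columns {sorted(missing)}")
        ratings = frame["rating"].to_numpy()
        if not np.isin(ratings, np.arange(1, 8)).all():
            raise ValueError("ratings must be integers in 1..7")
        self.frame = frame[list(self.COLUMNS)].copy()

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def counts(self) -> pd.Series:
        return self.frame.groupby("image_id")["rating"].count()


def _filled_hull(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Filled convex hull of (row, col) points as a boolean mask."""
    hull = ConvexHull(points)
    verts = points[hull.vertices]
    rr, cc = polygon(verts[:, 0], verts[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def build_mask(lm: LandmarkSet, kind: str, side: int,
               margin_frac: float = 0.04) -> RegionMask:
    """Landmark-derived scoring region.

    ``oral_nasal``: filled convex hull of the nose plus outer-mouth
    landmarks, dilated by ``margin_frac``·side. ``face_excluding_eyes``:
    filled hull of the jaw and brow outline minus the dilated eye hulls.
    """
    shape = (side, side)
    margin = max(1, int(round(margin_frac * side)))
    selem = disk(margin)
    pts = lm.points
    if kind == "oral_nasal":
        base = _filled_hull(pts[NOSE_IDX + OUTER_MOUTH_IDX], shape)
        mask = dilation(base, selem)
    elif kind == "face_excluding_eyes":
        face = dilation(_filled_hull(pts[JAW_IDX + BROW_IDX], shape),
                               selem)
        eyes = np.zeros(shape, dtype=bool)
        for idx in (RIGHT_EYE_IDX, LEFT_EYE_IDX):
            eyes |= dilation(_filled_hull(pts[idx], shape), selem)
        mask = face & ~eyes
    else:
        raise ValueError(f"unknown mask kind {kind!r}")
    if not mask.any():
        raise ValueError(f"mask {kind!r} selects no pixels for these landmarks")
    return RegionMask(mask, region_kind=kind)


def score(heat: Heatmap, mask: RegionMask,
          energy: str = "frobenius") -> AnomalyScore:
    """Negative-log masked heatmap energy.

    ``energy="frobenius"`` (default) uses the Frobenius norm of the masked
    map divided by the mask pixel count N; ``energy="mean"`` uses the plain
    masked mean. An all-zero masked heatmap (a perfect reconstruction)
    returns an infinite score with the ``perfectly_normal`` flag instead of
    raising, so batch scoring proceeds.
    """
    if heat.values.shape != mask.mask.shape:
        raise ValueError(
            f"heatmap {heat.values.shape} vs mask {mask.mask.shape}")
    masked = heat.values[mask.mask]
    n = mask.n_pixels
    if energy == "frobenius":
        raw = float(np.sqrt(np.sum(masked ** 2)) / n)
    elif energy == "mean":
        raw = float(masked.sum() / n)
    else:
        raise ValueError(f"unknown energy {energy!r}")
    if raw == 0.0:
        return AnomalyScore(raw_energy=0.0, score=np.inf,
                            mask_kind=mask.region_kind, method=heat.method,
                            ycbcr_applied=heat.ycbcr_applied,
                            erosion_applied=heat.erosion_applied,
                            perfectly_normal=True)
    return AnomalyScore(raw_energy=raw, score=float(-np.log(raw)),
                        mask_kind=mask.region_kind, method=heat.method,
                        ycbcr_applied=heat.ycbcr_applied,
                        erosion_applied=heat.erosion_applied)


def scale_scores(scores, interval: tuple[float, float] = (1.0, 7.0)):
    """Affine map of a score list onto ``interval`` (order preserved)."""
    arr = np.asarray(scores, dtype=np.float64)
    if arr.size < 2 or not np.isfinite(arr).all():
        raise ValueError("need at least 2 finite scores")
    lo, hi = interval
    span = arr.max() - arr.min()
    if span == 0:
        warnings.warn("all scores identical; returning interval midpoint")
        return np.full_like(arr, 0.5 * (lo + hi))
    return lo + (arr - arr.min()) * (hi - lo) / span


def aggregate_ratings(table: RatingTable, min_ratings: int = 20) -> pd.Series:
    """Per-image mean rating over images with at least ``min_ratings`` votes."""
    if min_ratings < 1:
        raise ValueError("min_ratings must be >= 1")
    grouped = table.frame.groupby("image_id")["rating"]
    counts = grouped.count()
    keep = counts[counts >= min_ratings].index
    if len(keep) == 0:
        raise ValueError(
            f"no image reaches the {min_ratings}-rating minimum")
    return grouped.mean().loc[keep]


def pearson(x, y) -> float:
    """Pearson product-moment correlation between two equal-length samples."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(pearsonr(x, y).statistic)
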