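"""Polygon areas and relative growth rates.

The tracked bead positions of each frame define a polygon approximating the
leaf blade. Its area follows the Gauss trapeze (shoelace) formula

    A = 0.5 * | sum_i (y_{i+1} x_i - y_i x_{i+1}) |      (indices mod n)

and the relative growth rate between two frames is

    RGR [% per frame] = (ln A_2 - ln A_1) / (f_2 - f_1) * 100
    RGR [% per hour]  = RGR [% per frame] * f_c,   f_c = 3600 / interval_s

``f_c`` is the time correction factor — the number of frames acquired per
hour (40 for the common 90 s acquisition interval).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

from .tracking import LOST, MarkerTrack

__all__ = [
    "GrowthSeries",
    "polygon_area",
    "rgr_per_frame",
    "time_correction_factor",
    "rgr_per_hour",
    "growth_series",
    "DegeneratePolygonWarning",
]


class DegeneratePolygonWarning(UserWarning):
    """Zero-area (collinear) or self-intersecting marker polygon."""


def polygon_area(corners) -> float:
    """Shoelace area of the polygon with the given ordered corners.

    The signed sum is wrapped in an absolute value, so clockwise and
    counter-clockwise corner orders give the same positive area. Collinear
    corners give 0 with a :class:`DegeneratePolygonWarning`.
    """
    pts = np.asarray(corners, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError(f"need >= 3 (x, y) corners, got array of shape {pts.shape}")
    x = pts[:, 0]
    y = pts[:, 1]
    x_next = np.roll(x, -1)
    y_next = np.roll(y, -1)
    area = 0.5 * abs(float(np.sum(y_next * x - y * x_next)))
    if area == 0.0:
        warnings.warn("polygon corners are collinear; area is 0", DegeneratePolygonWarning,
                      stacklevel=2)
    return area


def rgr_per_frame(area1: float, area2: float, f1: int, f2: int) -> float:
    """Relative growth rate in % per frame between frames ``f1 < f2``.

    Negative values indicate shrinkage.
    """
    if area1 <= 0 or area2 <= 0:
        raise ValueError(f"areas must be positive, got {area1}, {area2}")
    if f2 <= f1:
        raise ValueError(f"f2 must exceed f1, got f1={f1}, f2={f2}")
    return (math.log(area2) - math.log(area1)) / (f2 - f1) * 100.0


def time_correction_factor(interval_seconds: float) -> float:
    """Frames acquired per hour: ``f_c = 3600 / interval_seconds``."""
    if interval_seconds <= 0:
        raise ValueError(f"interval_seconds must be > 0, got {interval_seconds}")
    return 3600.0 / interval_seconds


def rgr_per_hour(rgr_frame, fc: float):
    """Convert % per frame to % per hour by the time correction factor."""
    if fc <= 0:
        raise ValueError(f"fc must be > 0, got {fc}")
    return rgr_frame * fc


@dataclass
class GrowthSeries:
    """Per-frame polygon area and derived RGR series.

    ``rgr_per_frame``/``rgr_per_hour`` have one entry per consecutive frame
    pair (length ``F - 1``); entry ``j`` covers frames ``j+1 -> j+2``.
    ``excluded`` flags frames in which any marker was lost; areas are still
    reported for them.
    """

    area: np.ndarray
    rgr_per_frame: np.ndarray
    rgr_per_hour: np.ndarray
    fc: float
    interval_seconds: float
    excluded: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.area.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tabular form matching the ``growth.csv`` schema.

        The RGR columns carry the rate of the pair ending at each frame, so
        frame 1 has no RGR (NaN).
        """
        f = np.arange(1, self.n_frames + 1)
        nanpad = np.full(1, np.nan)
        return pd.DataFrame({
            "frame_index": f,
            "time_seconds": (f - 1) * self.interval_seconds,
            "area": self.area,
            "rgr_percent_per_frame": np.concatenate([nanpad, self.rgr_per_frame]),
            "rgr_percent_per_hour": np.concatenate([nanpad, self.rgr_per_hour]),
            "excluded_flag": self.excluded.astype(bool),
        })


def _smooth_centered(series: np.ndarray, window: int) -> np.ndarray:
    if window % 2 == 0 or window < 1:
        raise ValueError(f"smoothing_window must be a positive odd integer, got {window}")
    return (
        pd.Series(series).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def growth_series(
    tracks: list[MarkerTrack],
    interval_seconds: float,
    smoothing_window: int | None = None,
    scale_mm_per_px: float | None = None,
) -> GrowthSeries:
    """Assemble the area and RGR time series from marker tracks.

    Corners are ordered by ascending marker id in every frame (never
    re-sorted spatially), areas come from :func:`polygon_area`, and RGR is
    computed for each consecutive frame pair. Frames containing a lost
    marker are flagged ``excluded`` but still carry an area.

    Parameters
    ----------
    smoothing_window
        Optional odd width of a centered moving average applied to both RGR
        series (default: no smoothing).
    scale_mm_per_px
        If given, areas are reported in mm^2 instead of px^2; RGR is
        unaffected (it is unit-free).
    """
    if not tracks:
        raise ValueError("no tracks given")
    lengths = {t.n_frames for t in tracks}
    if len(lengths) > 1:
        raise ValueError(f"tracks cover different frame counts: {sorted(lengths)}")
    F = lengths.pop()
    ordered = sorted(tracks, key=lambda t: t.marker_id)
    corners = np.stack([t.positions for t in ordered], axis=1)  # (F, n, 2)
    lost = np.stack(
        [np.asarray(t.status) == LOST for t in ordered], axis=1
    ).any(axis=1)

    simple = all(
        _ShapelyPolygon(corners[f]).is_valid for f in range(F)
    )
    if not simple:
        warnings.warn(
            "marker polygon is self-intersecting in at least one frame; areas "
            "are computed from the corner order as-is",
            DegeneratePolygonWarning, stacklevel=2,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegeneratePolygonWarning)
        areas = np.array([polygon_area(corners[f]) for f in range(F)])
    if scale_mm_per_px is not None:
        areas = areas * scale_mm_per_px**2

    rgr_f = np.array([
        rgr_per_frame(areas[j], areas[j + 1], j + 1, j + 2) for j in range(F - 1)
    ]) if F > 1 else np.empty(0)
    fc = time_correction_factor(interval_seconds)
    rgr_h = rgr_per_hour(rgr_f, fc)
    if smoothing_window is not None:
        rgr_f = _smooth_centered(rgr_f, smoothing_window)
        rgr_h = _smooth_centered(rgr_h, smoothing_window)
    return GrowthSeries(
        area=areas, rgr_per_frame=rgr_f, rgr_per_hour=rgr_h, fc=fc,
        interval_seconds=float(interval_seconds), excluded=lost,
    )
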