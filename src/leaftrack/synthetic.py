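"""Synthetic time-lapse scenes with ground truth.

Renders the measurement scene the tracker is designed for: a bright
artificial background, a darker leaf-blade polygon that grows exponentially
(optionally with a diel, 24 h-period modulation of the growth rate), and
small dark beads at the polygon corners serving as fiducial markers.
Optional disturbances — additive Gaussian sensor noise, a global affine
brightness drift, a moving brightness gradient, and bead occlusions — let
the tracker's robustness claims be exercised against exact ground truth.

Growth is applied as uniform scaling of the corner polygon about its
centroid so that the true area follows ``A(t) = A(0) * exp(∫ r(τ)/100 dτ)``
exactly (``r`` in % per hour, ``τ`` in hours). Beads are drawn with analytic
disc-coverage anti-aliasing, which keeps their true centers meaningful to
sub-pixel precision; rendered frames are quantized to a 16-bit intensity
grid, emulating the camera ADC and making the PNG round-trip exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as _raster_polygon

from .growth import polygon_area, rgr_per_frame, time_correction_factor
from .sequence import FrameSequence

__all__ = [
    "DielProfile",
    "SceneSpec",
    "GroundTruth",
    "generate_sequence",
    "apply_illumination",
    "render_frame",
    "regular_polygon",
    "ILLUMINATION_MODELS",
]

logger = logging.getLogger(__name__)

ILLUMINATION_MODELS = ("none", "global_affine_drift", "moving_gradient")


@dataclass(frozen=True)
class DielProfile:
    """Sinusoidal 24 h modulation of the growth rate, in % per hour.

    ``r(t) = baseline + amplitude * sin(2*pi*(t - peak_hour + 6)/24)`` peaks
    at ``t = peak_hour`` (hours since sequence start).
    """

    baseline: float
    amplitude: float
    peak_hour: float = 12.0

    def rate(self, t_hours: float) -> float:
        phase = 2.0 * math.pi * (t_hours - self.peak_hour + 6.0) / 24.0
        return self.baseline + self.amplitude * math.sin(phase)

    def integral(self, t_hours: float) -> float:
        """``∫_0^t r(τ) dτ`` in %·hours, closed form."""
        w = 2.0 * math.pi / 24.0
        phi = w * (6.0 - self.peak_hour)
        return self.baseline * t_hours + self.amplitude / w * (
            math.cos(phi) - math.cos(w * t_hours + phi)
        )


@dataclass
class SceneSpec:
    """Everything needed to render one ground-truthed sequence.

    Defaults mirror the measurement conditions the tracker targets: VGA
    frames, five beads, a 90 s acquisition interval, and a growth rate of
    2 % per hour.
    """

    image_size: tuple[int, int] = (640, 480)  # (width, height)
    n_markers: int = 5
    bead_radius_px: float = 5.0
    background_gray: float = 0.85
    leaf_gray: float = 0.45
    bead_gray: float = 0.10
    initial_polygon: np.ndarray | None = None  # (n, 2) of (x, y); default regular n-gon
    growth_rate_percent_per_hour: float | DielProfile = 2.0
    interval_seconds: float = 90.0
    n_frames: int = 100
    noise_sd: float = 0.01
    illumination: str = "none"
    occlusions: list[tuple[int, int]] | None = None  # (marker_id 1-based, from_frame 1-based)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 3:
            raise ValueError("need at least 3 markers")
        if not 0.0 < self.background_gray <= 1.0:
            raise ValueError("background_gray must lie in (0, 1]")
        if self.bead_gray >= self.leaf_gray:
            raise ValueError("beads must be darker than the leaf")
        if self.bead_gray >= self.background_gray:
            raise ValueError("beads must be darker than the background")
        if self.interval_seconds <= 0:
            raise ValueError("interval_seconds must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.illumination not in ILLUMINATION_MODELS:
            raise ValueError(
                f"unknown illumination model {self.illumination!r}; "
                f"choose from {ILLUMINATION_MODELS}"
            )
        if self.initial_polygon is None:
            w, h = self.image_size
            self.initial_polygon = regular_polygon(
                self.n_markers, center=(w / 2.0, h / 2.0),
                radius=0.30 * min(w, h),
            )
        else:
            self.initial_polygon = np.asarray(self.initial_polygon, dtype=np.float64)
            if self.initial_polygon.shape != (self.n_markers, 2):
                raise ValueError(
                    f"initial_polygon must have shape ({self.n_markers}, 2)"
                )

    def rate_integral_hours(self, t_hours: float) -> float:
        """``∫_0^t r(τ) dτ`` in %·hours for the configured growth profile."""
        r = self.growth_rate_percent_per_hour
        if isinstance(r, DielProfile):
            return r.integral(t_hours)
        return float(r) * t_hours


@dataclass
class GroundTruth:
    """Noise-free truth recorded while rendering a synthetic sequence."""

    centers: np.ndarray  # (F, n, 2) true marker centers (x, y)
    areas: np.ndarray  # (F,) true polygon area, px^2
    rgr_per_frame: np.ndarray  # (F-1,), % per frame
    rgr_per_hour: np.ndarray  # (F-1,), % per hour


def regular_polygon(n: int, center: tuple[float, float], radius: float) -> np.ndarray:
    """Corners of a regular n-gon (counter-clockwise, first corner up)."""
    ang = -math.pi / 2.0 + 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([
        center[0] + radius * np.cos(ang),
        center[1] + radius * np.sin(ang),
    ])


def _is_convex(corners: np.ndarray) -> bool:
    d = np.diff(np.vstack([corners, corners[:2]]), axis=0)
    cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
    return bool(np.all(cross >= 0) or np.all(cross <= 0))


def _leaf_coverage(corners: np.ndarray, height: int, width: int) -> np.ndarray:
    """Per-pixel coverage of the leaf polygon in [0, 1].

    Convex polygons get a linear anti-aliased edge from the signed distance
    to the boundary (max over outward edge half-planes); non-convex ones
    fall back to hard rasterization.
    """
    if not _is_convex(corners):
        mask = np.zeros((height, width), dtype=np.float64)
        rr, cc = _raster_polygon(corners[:, 1], corners[:, 0], shape=(height, width))
        mask[rr, cc] = 1.0
        return mask
    # ensure counter-clockwise in (x, y) with y downward => signed area < 0 is CW
    x, y = corners[:, 0], corners[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    pts = corners if signed > 0 else corners[::-1]
    yy, xx = np.mgrid[0:height, 0:width]
    d = np.full((height, width), -np.inf)
    n = len(pts)
    for i in range(n):
        p, q = pts[i], pts[(i + 1) % n]
        ex, ey = q - p
        norm = math.hypot(ex, ey)
        # outward normal of a CCW edge in image coordinates (y down)
        nx, ny = ey / norm, -ex / norm
        np.maximum(d, (xx - p[0]) * nx + (yy - p[1]) * ny, out=d)
    return np.clip(0.5 - d, 0.0, 1.0)


def _paint_disc(frame: np.ndarray, center: tuple[float, float], radius: float,
                gray: float) -> None:
    """Blend an anti-aliased disc into ``frame`` in place."""
    h, w = frame.shape
    cx, cy = center
    pad = int(math.ceil(radius)) + 2
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    frame[y0:y1, x0:x1] = frame[y0:y1, x0:x1] * (1.0 - cov) + gray * cov


def render_frame(
    spec: SceneSpec, corners: np.ndarray,
    occluded: set[int] | frozenset[int] = frozenset(),
) -> np.ndarray:
    """Render one noise-free, unlit frame for the given true corners.

    Beads whose 1-based marker id is in ``occluded`` are painted over with a
    background-gray disc of twice the bead radius, emulating bead removal.
    """
    w, h = spec.image_size
    cov = _leaf_coverage(corners, h, w)
    frame = spec.background_gray * (1.0 - cov) + spec.leaf_gray * cov
    for k, (cx, cy) in enumerate(corners, start=1):
        if k in occluded:
            _paint_disc(frame, (cx, cy), 2.0 * spec.bead_radius_px, spec.background_gray)
        else:
            _paint_disc(frame, (cx, cy), spec.bead_radius_px, spec.bead_gray)
    return frame


def apply_illumination(frame: np.ndarray, model: str, frame_index: int,
                       seed: int = 0) -> np.ndarray:
    """Apply one of the supported illumination disturbance models.

    ``global_affine_drift`` maps ``i -> a(f)*i + b(f)`` with smoothly
    varying gain ``a(f) > 0`` and offset ``b(f)``; ``moving_gradient`` adds
    a linear brightness ramp whose direction rotates slowly over frames.
    Results are clipped to [0, 1]; any clipping is logged.
    """
    if model not in ILLUMINATION_MODELS:
        raise ValueError(
            f"unknown illumination model {model!r}; choose from {ILLUMINATION_MODELS}"
        )
    if model == "none":
        return frame
    f = frame_index
    if model == "global_affine_drift":
        a = 1.0 + 0.08 * math.sin(2.0 * math.pi * f / 240.0)
        b = 0.04 * math.sin(2.0 * math.pi * f / 377.0 + 1.0)
        out = a * frame + b
    else:  # moving_gradient
        h, w = frame.shape
        theta = 2.0 * math.pi * f / 500.0
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (math.cos(theta) * (xx - w / 2.0) + math.sin(theta) * (yy - h / 2.0))
        out = frame + 0.05 * ramp / max(h, w)
    clipped = np.count_nonzero((out < 0.0) | (out > 1.0))
    if clipped:
        logger.warning(
            "illumination model %s clipped %.3f%% of pixels in frame %d",
            model, 100.0 * clipped / out.size, f,
        )
    return np.clip(out, 0.0, 1.0)


def _quantize16(frame: np.ndarray) -> np.ndarray:
    """Snap to the 16-bit ADC grid, as stored in the output PNGs."""
    levels = np.round(np.clip(frame, 0.0, 1.0) * 65535.0).astype(np.uint16)
    return (levels.astype(np.float32) / np.float32(65535.0)).astype(np.float32)


def generate_sequence(spec: SceneSpec) -> tuple[FrameSequence, GroundTruth]:
    """Render the full ground-truthed sequence described by ``spec``.

    Frame ``f`` scales the initial polygon about its centroid so that the
    true area is ``A(1) * exp(∫ r/100 dt)``; ground truth (centers, areas,
    RGR) is recorded before noise and illumination are applied. The same
    spec and seed always produce bit-identical pixel data.

    Raises
    ------
    ValueError
        If a bead grows past the image bounds; the message names the first
        offending frame.
    """
    w, h = spec.image_size
    corners0 = spec.initial_polygon
    centroid = corners0.mean(axis=0)
    F = spec.n_frames
    rng = np.random.default_rng(spec.seed)

    occlusion_from = {}
    for mid, from_frame in (spec.occlusions or []):
        if not 1 <= mid <= spec.n_markers:
            raise ValueError(f"occlusion refers to unknown marker {mid}")
        occlusion_from[mid] = from_frame

    frames = np.empty((F, h, w), dtype=np.float32)
    centers = np.empty((F, spec.n_markers, 2))
    areas = np.empty(F)
    margin = spec.bead_radius_px + 1.0
    for f in range(F):
        t_hours = f * spec.interval_seconds / 3600.0
        scale = math.exp(spec.rate_integral_hours(t_hours) / 200.0)  # sqrt of area ratio
        corners = centroid + scale * (corners0 - centroid)
        if (corners[:, 0].min() < margin or corners[:, 1].min() < margin
                or corners[:, 0].max() > w - 1 - margin
                or corners[:, 1].max() > h - 1 - margin):
            raise ValueError(
                f"polygon grows beyond the image bounds at frame {f + 1}"
            )
        occluded = {mid for mid, start in occlusion_from.items() if f + 1 >= start}
        frame = render_frame(spec, corners, occluded)
        frame = apply_illumination(frame, spec.illumination, f + 1, spec.seed)
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, frame.shape)
        frames[f] = _quantize16(frame)
        centers[f] = corners
        areas[f] = polygon_area(corners)

    rgr_f = np.array([
        rgr_per_frame(areas[j], areas[j + 1], j + 1, j + 2) for j in range(F - 1)
    ]) if F > 1 else np.empty(0)
    fc = time_correction_factor(spec.interval_seconds)
    truth = GroundTruth(centers=centers, areas=areas, rgr_per_frame=rgr_f,
                        rgr_per_hour=rgr_f * fc)
    seq = FrameSequence(frames, spec.interval_seconds)
    return seq, truth
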