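"""Block-matching bead tracker.

Each bead marker is represented by a fixed square template cut around its
position in the first frame. In every later frame the template is compared,
by normalized cross-correlation (NCC), against all candidate windows inside
a search region centered on the marker's position in the last investigated
frame. The integer-pixel correlation peak is refined to subpixel precision
by fitting a parabola through the peak and its two axis neighbors. A peak
whose correlation falls below a quality threshold (default 0.7) marks the
marker "not found" for that frame.

NCC is mean-subtracted and variance-normalized per window, so a positive
affine change of image gray values (``a*i + b`` with ``a > 0``) leaves the
correlation surface unchanged — the tracker does not require constant scene
brightness, unlike optical-flow approaches built on the brightness-change
constraint equation.

Coordinates are 0-based with ``x`` = column and ``y`` = row; pixel centers
sit at integer coordinates, and positions are reported as real ``(x, y)``
pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .sequence import FrameSequence

__all__ = [
    "TemplatePatch",
    "SearchRegion",
    "CorrelationSurface",
    "PeakResult",
    "MarkerTrack",
    "NoDefinedCorrelationError",
    "TRACKED",
    "LOST",
    "extract_template",
    "ncc_surface",
    "locate_peak",
    "subpixel_peak",
    "track_markers",
    "round_half_away",
]

logger = logging.getLogger(__name__)

TRACKED = "tracked"
LOST = "lost"

DEFAULT_CC_THRESHOLD = 0.7
# windows whose intensity variance falls below this are treated as flat:
# the correlation is undefined there rather than 0/0
_VAR_EPS = 1e-12


class NoDefinedCorrelationError(ValueError):
    """Raised when every candidate window yields an undefined correlation."""


def round_half_away(v: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    v = np.asarray(v)
    out = np.sign(v) * np.floor(np.abs(v) + 0.5)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TemplatePatch:
    """Fixed reference patch cut around a marker in its source frame."""

    pixels: np.ndarray
    origin_center: tuple[int, int]  # (x, y) in the source frame
    source_frame: int = 1

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"template must be square, got shape {px.shape}")
        if px.shape[0] % 2 == 0:
            raise ValueError(f"template side must be odd, got {px.shape[0]}")
        px.flags.writeable = False
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def mean_gray(self) -> float:
        return float(self.pixels.mean())


@dataclass(frozen=True)
class SearchRegion:
    """Search window parameters around a marker's last known position.

    Candidate template placements span integer displacements
    ``(dx, dy) in [-L, L]^2`` relative to the placement implied by ``center``.
    """

    center: tuple[float, float]  # (x, y), real; rounded for window placement
    search_length: int

    def __post_init__(self) -> None:
        if self.search_length < 1:
            raise ValueError(f"search_length must be >= 1, got {self.search_length}")


@dataclass
class CorrelationSurface:
    """NCC values over the (2L+1)^2 search grid for one marker and frame.

    ``values[dy + L, dx + L]`` is the correlation at displacement
    ``(dx, dy)``; NaN marks displacements where the correlation is undefined
    (window off the frame, or zero variance).
    """

    values: np.ndarray
    search_length: int
    peak_offset: tuple[int, int] = field(init=False)
    cc_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        L = self.search_length
        if self.values.shape != (2 * L + 1, 2 * L + 1):
            raise ValueError(
                f"values must be {(2 * L + 1, 2 * L + 1)}, got {self.values.shape}"
            )
        if not np.isfinite(self.values).any():
            raise NoDefinedCorrelationError(
                "no defined correlation value in the search region"
            )
        # first maximum in row-major (y then x) scan order
        flat = np.where(np.isfinite(self.values), self.values, -np.inf).ravel()
        idx = int(np.argmax(flat))
        iy, ix = divmod(idx, self.values.shape[1])
        self.peak_offset = (ix - L, iy - L)
        self.cc_max = float(self.values[iy, ix])

    def value_at(self, dx: int, dy: int) -> float:
        """Correlation at displacement (dx, dy); NaN outside or undefined."""
        L = self.search_length
        iy, ix = dy + L, dx + L
        if not (0 <= iy <= 2 * L and 0 <= ix <= 2 * L):
            return float("nan")
        return float(self.values[iy, ix])


@dataclass(frozen=True)
class PeakResult:
    accepted: bool
    offset: tuple[int, int]
    cc_max: float


@dataclass
class MarkerTrack:
    """Per-frame subpixel positions and quality of one bead marker."""

    marker_id: int
    positions: np.ndarray  # (F, 2) of (x, y)
    status: list[str]  # per frame, TRACKED or LOST
    cc_history: np.ndarray  # (F,), NaN for frame 1 and lost frames

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def lost_frames(self) -> np.ndarray:
        """1-based frame indices where the marker was not found."""
        return np.flatnonzero(np.asarray(self.status) == LOST) + 1


def extract_template(
    frame: np.ndarray, center: tuple[int, int], template_size: int, *,
    marker_id: int | None = None, source_frame: int = 1,
) -> TemplatePatch:
    """Cut the square template of odd side ``template_size`` around ``center``.

    The patch is an immutable copy: later edits of the frame do not affect it.

    Raises
    ------
    ValueError
        If ``template_size`` is even, or the patch would cross the frame
        border (the error names the marker and frame when given).
    """
    frame = np.asarray(frame)
    if template_size % 2 == 0 or template_size < 1:
        raise ValueError(f"template_size must be a positive odd integer, got {template_size}")
    half = template_size // 2
    cx, cy = int(center[0]), int(center[1])
    h, w = frame.shape
    if cx - half < 0 or cy - half < 0 or cx + half >= w or cy + half >= h:
        who = f"marker {marker_id} " if marker_id is not None else ""
        raise ValueError(
            f"template of size {template_size} around ({cx}, {cy}) for {who}"
            f"crosses the border of frame {source_frame} ({w}x{h})"
        )
    patch = frame[cy - half : cy + half + 1, cx - half : cx + half + 1].copy()
    return TemplatePatch(patch, origin_center=(cx, cy), source_frame=source_frame)


def _ncc_values_loop(
    frame: np.ndarray, t: np.ndarray, tops: np.ndarray, lefts: np.ndarray
) -> np.ndarray:
    """Per-candidate NCC evaluation with border candidates dropped (NaN)."""
    h, w = frame.shape
    s = t.shape[0]
    tc = t - t.mean()
    tvar = float((tc * tc).sum())
    out = np.full((tops.shape[0], lefts.shape[0]), np.nan)
    if tvar <= _VAR_EPS:
        return out
    n_px = s * s
    for iy, top in enumerate(tops):
        if top < 0 or top + s > h:
            continue
        for ix, left in enumerate(lefts):
            if left < 0 or left + s > w:
                continue
            win = frame[top : top + s, left : left + s]
            wc = win - win.mean()
            wvar = float((wc * wc).sum())
            if wvar <= _VAR_EPS * n_px:
                continue
            out[iy, ix] = float((wc * tc).sum()) / np.sqrt(wvar * tvar)
    return out


def _ncc_values_fast(frame: np.ndarray, t: np.ndarray, top0: int, left0: int, L: int) -> np.ndarray:
    """Vectorized NCC over the full (2L+1)^2 grid; requires the whole
    search block to lie inside the frame."""
    s = t.shape[0]
    block = frame[top0 - L : top0 + L + s, left0 - L : left0 + L + s]
    win = sliding_window_view(block, (s, s))  # (2L+1, 2L+1, s, s)
    tc = t - t.mean()
    tvar = float((tc * tc).sum())
    n_px = s * s
    out = np.full(win.shape[:2], np.nan)
    if tvar <= _VAR_EPS:
        return out
    wsum = np.einsum("ijmn->ij", win)
    # sum of (w - mean_w)(t - mean_t) = sum of w * (t - mean_t), since tc sums to 0
    cross = np.einsum("ijmn,mn->ij", win, tc)
    ssq = np.einsum("ijmn,ijmn->ij", win, win)
    wvar = ssq - wsum * wsum / n_px
    defined = wvar > _VAR_EPS * n_px
    np.divide(cross, np.sqrt(wvar * tvar, where=defined, out=np.ones_like(wvar)),
              where=defined, out=out)
    return out


def ncc_surface(
    frame: np.ndarray, template: TemplatePatch, region: SearchRegion
) -> CorrelationSurface:
    """Normalized cross-correlation of ``template`` over the search region.

    For each candidate top-left ``(x, y)``::

        CC(x, y) = sum((i_win - I_xy) * (t - T))
                   / sqrt(sum((i_win - I_xy)^2) * sum((t - T)^2))

    with ``I_xy`` the mean of the image window and ``T`` the template mean.
    Candidate windows extending past the frame border are dropped (not
    padded); windows or templates with zero variance yield NaN.

    Raises
    ------
    NoDefinedCorrelationError
        If every candidate value is undefined.
    """
    frame = np.asarray(frame, dtype=np.float64)
    t = template.pixels
    s = template.size
    if s > min(frame.shape):
        raise ValueError(f"template side {s} exceeds frame {frame.shape}")
    L = region.search_length
    half = s // 2
    cx = int(round_half_away(region.center[0]))
    cy = int(round_half_away(region.center[1]))
    top0, left0 = cy - half, cx - half  # candidate placement at zero displacement
    h, w = frame.shape
    if top0 - L >= 0 and left0 - L >= 0 and top0 + L + s <= h and left0 + L + s <= w:
        values = _ncc_values_fast(frame, t, top0, left0, L)
    else:
        tops = top0 + np.arange(-L, L + 1)
        lefts = left0 + np.arange(-L, L + 1)
        values = _ncc_values_loop(frame, t, tops, lefts)
    return CorrelationSurface(values, search_length=L)


def locate_peak(
    surface: CorrelationSurface, cc_threshold: float = DEFAULT_CC_THRESHOLD
) -> PeakResult:
    """Integer peak of the correlation surface and the quality decision.

    The marker is accepted when ``cc_max >= cc_threshold``; a correlation
    maximum below the threshold means the template is regarded as not found.
    Ties resolve to the first maximum in row-major (y then x) scan order.
    """
    return PeakResult(
        accepted=surface.cc_max >= cc_threshold,
        offset=surface.peak_offset,
        cc_max=surface.cc_max,
    )


def _parabola_offset(c_minus: float, c0: float, c_plus: float) -> float:
    """Vertex abscissa of the parabola through (-1, c-), (0, c0), (+1, c+).

    Returns 0 for non-concave or degenerate triples; result clamped to
    [-0.5, 0.5] (the quadratic model is only trusted near an interior peak).
    """
    if not (np.isfinite(c_minus) and np.isfinite(c_plus)):
        return 0.0
    denom = 2.0 * (c_minus - 2.0 * c0 + c_plus)
    if denom >= 0.0:
        return 0.0
    delta = (c_minus - c_plus) / denom
    return float(np.clip(delta, -0.5, 0.5))


def subpixel_peak(surface: CorrelationSurface) -> tuple[float, float]:
    """Refine the integer correlation peak to subpixel precision.

    Per axis, the maximum of the quadratic polynomial through the peak value
    and its two neighbors gives the subpixel displacement; a missing neighbor
    (peak on the border of the defined region) or a non-concave fit leaves
    that axis unrefined.

    Returns
    -------
    (dx, dy)
        Real displacement: integer peak offset plus per-axis refinement.
    """
    dx0, dy0 = surface.peak_offset
    c0 = surface.cc_max
    ddx = _parabola_offset(surface.value_at(dx0 - 1, dy0), c0, surface.value_at(dx0 + 1, dy0))
    ddy = _parabola_offset(surface.value_at(dx0, dy0 - 1), c0, surface.value_at(dx0, dy0 + 1))
    return (dx0 + ddx, dy0 + ddy)


def _pairwise_min_distance(points: np.ndarray) -> float:
    d = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((d * d).sum(-1))
    np.fill_diagonal(dist, np.inf)
    return float(dist.min())


def track_markers(
    sequence: FrameSequence,
    initial_positions: list[tuple[float, float]] | np.ndarray,
    template_size: int = 23,
    search_length: int = 6,
    cc_threshold: float = DEFAULT_CC_THRESHOLD,
    marker_ids: list[int] | None = None,
) -> list[MarkerTrack]:
    """Track every marker through the whole sequence.

    Templates are extracted once from frame 1 and never updated. For each
    later frame the search region is centered on the marker's position in
    the last investigated frame (tracked or carried forward), rounded to the
    nearest pixel. Accepted matches yield subpixel positions; rejected
    matches flag the frame lost and carry the last position forward, so the
    marker can be reacquired if it reappears near that position.

    Parameters
    ----------
    initial_positions
        Integer (x, y) bead centers in frame 1, one per marker; at least 3.
    template_size
        Odd side length of the fixed template (default 23).
    search_length
        Maximum displacement explored per axis per frame (default 6).
    cc_threshold
        Minimum correlation for a match to count as found (default 0.7).
    """
    pos0 = np.asarray(initial_positions, dtype=np.float64)
    if pos0.ndim != 2 or pos0.shape[1] != 2 or pos0.shape[0] < 3:
        raise ValueError("need at least 3 markers as (x, y) pairs")
    n_markers = pos0.shape[0]
    if marker_ids is None:
        marker_ids = list(range(1, n_markers + 1))
    if len(marker_ids) != n_markers:
        raise ValueError("marker_ids length must match initial_positions")
    min_dist = _pairwise_min_distance(pos0)
    if search_length >= min_dist:
        warnings.warn(
            f"search_length {search_length} is not smaller than the closest "
            f"inter-marker distance {min_dist:.1f} px; templates may lock onto "
            "a neighboring bead",
            stacklevel=2,
        )

    F = sequence.n_frames
    templates = [
        extract_template(sequence.frames[0], (int(round_half_away(x)), int(round_half_away(y))),
                         template_size, marker_id=mid, source_frame=1)
        for (x, y), mid in zip(pos0, marker_ids)
    ]

    tracks = []
    for k, (template, mid) in enumerate(zip(templates, marker_ids)):
        positions = np.empty((F, 2))
        cc_hist = np.full(F, np.nan)
        status = [TRACKED]
        positions[0] = pos0[k]
        current = pos0[k].copy()
        for f in range(1, F):
            region = SearchRegion(center=(current[0], current[1]), search_length=search_length)
            try:
                surface = ncc_surface(sequence.frames[f], template, region)
            except NoDefinedCorrelationError:
                logger.warning(
                    "marker %s frame %d: no defined correlation (search window "
                    "off-frame or flat); carrying last position forward", mid, f + 1,
                )
                positions[f] = current
                status.append(LOST)
                continue
            peak = locate_peak(surface, cc_threshold)
            if peak.accepted:
                dx, dy = subpixel_peak(surface)
                current = np.array([
                    round_half_away(current[0]) + dx,
                    round_half_away(current[1]) + dy,
                ])
                positions[f] = current
                cc_hist[f] = peak.cc_max
                status.append(TRACKED)
            else:
                logger.info(
                    "marker %s frame %d: cc_max %.3f below threshold %.2f, "
                    "marked lost", mid, f + 1, peak.cc_max, cc_threshold,
                )
                positions[f] = current
                status.append(LOST)
        tracks.append(MarkerTrack(mid, positions, status, cc_hist))
    return tracks
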