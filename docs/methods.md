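# Methods

## The measurement model

`leaftrack` quantifies leaf expansion from a time-lapse sequence of
grayscale images in which small dark beads, glued to the leaf margin over a
bright artificial background, serve as fiducial markers. The method makes
three assumptions:

1. **Markers are rigid landmarks.** Each bead moves with the leaf margin
   point it is attached to; its appearance (a dark disc plus a fragment of
   the leaf edge) changes little over the sequence.
2. **Motion is slow relative to sampling.** Between consecutive frames a
   bead moves at most `search_length` pixels per axis (default 6 at a 90 s
   interval; leaf margins move far less than that per 90 s).
3. **The marker polygon is a proxy for blade area.** With `n ≥ 3` markers
   on the margin, the polygon they span scales with the blade, so the
   *relative* growth rate of the polygon equals that of the blade even
   though the absolute areas differ. Within-leaf growth gradients are
   deliberately out of scope.

## Tracking

A fixed template is cut once around each marker in frame 1 and never
updated; adaptive template updating is intentionally absent (it trades
drift for appearance tolerance, and the bead appearance is stable by
design). For each later frame, the normalized cross-correlation

```
CC(x,y) = Σ (i_win − I_xy)(t − T) / sqrt( Σ (i_win − I_xy)² · Σ (t − T)² )
```

is evaluated for all `(2L+1)²` candidate placements centered on the
marker's position in the last investigated frame (rounded half-away-from-
zero to an integer pixel). Implementation notes:

- **Border handling.** Candidate windows extending past the frame are
  dropped from the search set, not padded: padding fabricates intensities
  and biases the correlation.
- **Degenerate windows.** A window (or template) with intensity variance
  ≤ 1e−12 per pixel has no defined correlation; such cells are NaN and are
  excluded from the maximum. If *every* cell is undefined the frame raises
  a "no defined correlation" error, which the tracking loop converts to a
  lost frame.
- **Tie-break.** Equal maxima resolve to the first in row-major (y, x)
  scan order — deterministic and oracle-checkable.
- **Quality threshold.** `CC_max < 0.7` marks the marker *not found* for
  the frame. The position is then carried forward and the search continues
  from it in later frames: beads are physically constrained, so
  reacquisition near the last position is plausible. Frames containing any
  lost marker are still evaluated but flagged `excluded` in the growth
  output.
- **Subpixel refinement.** Per axis, the vertex of the parabola through
  `(−1, c₋), (0, c₀), (+1, c₊)`, i.e. `δ = (c₋ − c₊) / (2(c₋ − 2c₀ + c₊))`,
  clamped to `|δ| ≤ 0.5`; a missing neighbor (peak on the border of the
  defined region) or a non-concave triple leaves the axis unrefined
  (δ = 0). The parabola is applied even when `c₀ = 1`: the interpolator is
  defined by its three-point formula, and special-casing a perfect match
  would change the documented estimator. One consequence is that a
  perfectly static scene can show a one-time sub-0.02 px offset at frame 2
  (the peak's neighbors need not be symmetric), after which positions are
  constant.
- **Accuracy.** Three-point parabola refinement on sharp-edged targets has
  a known pixel-locking bias; for the default bead model the worst
  recovered-shift error is ≈ 0.1 px, the practical accuracy limit of this
  estimator. Users needing better should use larger/smoother markers, not
  a larger template.
- **Coordinates.** 0-based, `x` = column, `y` = row, pixel centers at
  integer coordinates; positions are real `(x, y)` pairs.

NCC is invariant to per-frame affine gray changes `a·i + b` (a > 0)
because both mean subtraction and variance normalization cancel `a` and
`b` exactly. This is why the tracker needs no brightness-constancy
assumption, unlike optical-flow growth analysis; the test suite checks the
invariance both algebraically (identical correlation surfaces) and
end-to-end (tracking error unchanged within 0.05 px under a drifting
global gain/offset).

## Growth math

Areas use the shoelace formula with an absolute value, so clockwise and
counter-clockwise marker orders agree. Corner order is the marker-id order
and is never re-sorted; a self-intersecting order is computed as-is but
warned about once per series. RGR is computed per consecutive frame pair,
`100·(ln A_{f+1} − ln A_f)`, and converted to %/hour by
`f_c = 3600/interval`. The per-frame series telescopes:
`Σ RGR/100 = ln(A_F/A_1)`, which the tests verify to 1e−9. Optional
smoothing is a centered moving average of odd width (default: none, since
the raw series is already an exact log-difference); areas can be reported
in mm² via an optional mm-per-pixel scale, which leaves RGR unchanged.

## The synthetic scene generator

`SceneSpec` renders the scene the tracker targets: a bright background
(gray 0.85), a darker leaf polygon (0.45), and dark beads (0.10, radius
5 px) at the polygon corners, 640 × 480 by default, sampled every 90 s.
Growth scales the corner polygon uniformly about its centroid so the true
area follows `A(t) = A(0)·exp(∫ r(τ)/100 dτ)` exactly, with `r` either
constant (default 2 %/h) or a 24 h sinusoid (`DielProfile`). Ground truth
(corner positions, areas, RGR) is recorded before noise and illumination.

Rendering choices that matter:

- **Bead anti-aliasing** uses analytic disc coverage
  (`clip(r + 0.5 − dist, 0, 1)`, a linear one-pixel edge), so true centers
  are meaningful to sub-pixel precision; integer-only rendering would make
  subpixel accuracy untestable. Exact pixel-area coverage was evaluated
  and does not measurably change tracking accuracy.
- **Leaf anti-aliasing**: convex polygons get the same linear edge from
  the signed distance (max over edge half-planes); non-convex polygons
  fall back to hard rasterization, which is accurate to ±0.5 px only.
- **Occlusion** paints a background-gray disc of twice the bead radius
  over the marker from its occlusion frame on, emulating bead removal.
- **Illumination**: `global_affine_drift` applies a smoothly varying
  per-frame gain (±8 %) and offset (±0.04); `moving_gradient` adds a
  slowly rotating linear ramp (amplitude 0.05). Values are clipped to
  [0, 1] and clipping is logged; the default parameters do not clip.
- **Sensor model**: Gaussian noise (sd 0.01 by default) is added after
  illumination, then intensities are quantized to the 16-bit ADC grid
  (`k/65535`). Quantization makes the PNG round-trip bit-exact and is the
  only nonlinearity in the chain.
- **Determinism**: all randomness flows from `spec.seed` through one
  `numpy` generator; identical specs give bit-identical sequences.

What the generator does *not* emulate: leaf texture and venation, specular
reflections, non-uniform (base-to-tip) growth, bead detachment drift,
camera shake, or automatic-gain artifacts beyond the affine model. Passing
tests therefore demonstrate the correctness of the tracking and growth
machinery under controlled conditions, not field performance on real
canopies.

## Problem sizes used in validation

The long-sequence validation runs 3460 frames (86.5 h at 90 s/frame) at
320 × 240 with the polygon started at 55 % of its default size so that
2 %/h of growth stays inside the frame; a full-length sequence at the
default 640 × 480 would hold ~4 GiB of frames in memory for no additional
coverage, since tracking accuracy is set by the local bead neighborhood,
not the frame size. Shorter checks (illumination robustness, occlusion)
use 40–60 frames at 240 × 200.

## Known limitations

- Fixed templates drift-proof the tracker but fail if bead appearance
  changes substantially (strong perspective change, partial occlusion).
- The quadratic interpolator's ~0.1 px worst-case bias bounds subpixel
  accuracy; RGR estimates over long sequences are far more precise than
  single displacements because log-area increments telescope.
- The lost-marker policy (hold position, keep searching) can silently
  mis-reacquire if a different dark object enters the search window; the
  `excluded` flags and `cc_max` column in `tracks.csv` should be inspected
  whenever markers were lost.
- One inter-frame interval applies to the whole sequence; wall-clock
  timestamps per frame are not supported (`time_seconds` is
  `(frame_index − 1) · interval`).
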