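# leaftrack

Marker-based leaf growth analysis for time-lapse imaging.

Plant physiologists measure diel (24 h) leaf growth rhythms by filming a
leaf — typically under near-infrared illumination so day and night look the
same to the camera — and quantifying how fast its area expands. Natural
leaf texture is a fragile tracking target: it is low-contrast, it deforms,
and optical-flow methods additionally require near-constant scene
brightness. `leaftrack` instead tracks small dark beads glued to the leaf
margin as fiducial markers, which works outdoors, under drifting
illumination, and over multi-day sequences.

## Method

Each bead is selected once in the first frame, and a fixed square template
`t` (default 23 × 23 px) is cut around it. In every later frame the
template is matched, within a search window of ± `L` px (default 6) around
the marker's last position, by normalized cross-correlation

```
            Σ_{m,n} (i(x+m, y+n) − I_xy) (t(m,n) − T)
CC(x,y) = ─────────────────────────────────────────────────
          √( Σ (i(x+m,y+n) − I_xy)²  ·  Σ (t(m,n) − T)² )
```

where `I_xy` and `T` are the window and template mean gray values. Because
`CC` is mean-subtracted and variance-normalized, any gray mapping
`i → a·i + b` (a > 0) leaves it unchanged — brightness constancy is not
required. The best integer position is the maximum `CC_max`; a match with
`CC_max < 0.7` flags the marker *lost* for that frame. The integer peak is
refined per axis to subpixel precision by the vertex of the parabola
through `CC_max` and its two neighbors.

The `n ≥ 3` tracked markers form a polygon whose area follows the shoelace
(Gauss trapeze) formula `A = ½ |Σ_i (y_{i+1} x_i − y_i x_{i+1})|` (indices
mod n), and growth is reported as a relative growth rate (RGR):

```
RGR [%/frame] = (ln A₂ − ln A₁) / (f₂ − f₁) · 100
RGR [%/hour]  = RGR [%/frame] · f_c ,   f_c = 3600 / interval_seconds
```

`f_c` is the time correction factor — the number of frames per hour (40
for the common 90 s interval).

A synthetic scene generator (`leaftrack.synthetic`) renders ground-truthed
sequences — bright background, growing leaf polygon, anti-aliased dark
beads, sensor noise, illumination drift, bead occlusions — so the whole
pipeline is testable without real image data.

## Worked example

`examples/01_track_and_growth.py` renders a 400-frame scene growing at
2 %/h (one frame per 90 s), tracks the five corner beads, and recovers the
growth rate:

```
frames tracked: 400, markers: 5
mean tracking error: 0.397 px (worst 0.652 px)
time correction factor f_c = 40 frames/hour
area grew from 12200 to 14883 px^2
mean recovered RGR: 1.993 %/h (true rate: 2.000 %/h)
```

The tracking error is the distance between recovered and true bead
centers; the recovered RGR agrees with the generated rate to well under
0.1 %/h. `examples/02_illumination_robustness.py` shows the affine
brightness invariance (tracking error changes by ~5 · 10⁻⁴ px under a
drifting gain/offset), and `examples/03_lost_marker_and_diel_growth.py`
demonstrates the lost-marker threshold and a recovered day/night growth
rhythm.

## Command line

```
leaftrack simulate --spec scene.yaml --out sim/         # render a scene + ground truth
leaftrack track --input sim/ --markers markers.csv \
          --template-size 23 --search-length 6 \
          --cc-threshold 0.7 --interval 90 --out run/   # tracks.csv, growth.csv, run_log.json
leaftrack analyze --tracks run/tracks.csv --interval 90 --out growth/
```

`markers.csv` has columns `marker_id,x,y` with the bead centers in the
first frame (0-based pixel coordinates, x = column). Outputs are plain CSV
with a fixed dialect, so re-running a configuration reproduces files
byte-for-byte.

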