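"""Track beads on a synthetic growing leaf and recover its growth rate.

Renders a short ground-truthed sequence (a leaf polygon growing at 2 % per
hour, imaged every 90 s), tracks the five corner beads by normalized
cross-correlation, and converts the marker-polygon area into relative
growth rates. The printed mean RGR should sit near the 2 %/h the scene was
generated with; the residual tracking error shows the subpixel quality.
"""

import numpy as np

from leaftrack import SceneSpec, generate_sequence, growth_series, track_markers

spec = SceneSpec(image_size=(320, 240), n_frames=400, noise_sd=0.01,
                 growth_rate_percent_per_hour=2.0, interval_seconds=90.0, seed=8)
seq, truth = generate_sequence(spec)

tracks = track_markers(seq, np.round(truth.centers[0]),
                       template_size=23, search_length=6)
pos = np.stack([t.positions for t in tracks], axis=1)
err = np.linalg.norm(pos - truth.centers, axis=2)
print(f"frames tracked: {seq.n_frames}, markers: {len(tracks)}")
print(f"mean tracking error: {err.mean():.3f} px (worst {err.max():.3f} px)")

series = growth_series(tracks, spec.interval_seconds)
print(f"time correction factor f_c = {series.fc:g} frames/hour")
print(f"area grew from {series.area[0]:.0f} to {series.area[-1]:.0f} px^2")
print(f"mean recovered RGR: {series.rgr_per_hour.mean():.3f} %/h "
      f"(true rate: 2.000 %/h)")
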