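"""CSV plumbing for marker files, track tables and growth tables.

The dialect is fixed so outputs are byte-reproducible: comma separators,
dot decimals, a header row, UTF-8, LF line endings, floats printed with 10
significant digits (re-parsing reproduces in-memory values to printed
precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthSeries
from .tracking import LOST, TRACKED, MarkerTrack

__all__ = [
    "read_markers",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_growth_csv",
]

_FLOAT_FMT = "{:.10g}"


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return _FLOAT_FMT.format(float(v))
    return str(v)


def _write_table(path: Path, header: list[str], rows) -> None:
    lines = [",".join(header)]
    lines.extend(",".join(_fmt(v) for v in row) for row in rows)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_markers(path: str | Path) -> tuple[list[int], np.ndarray]:
    """Read the initial marker table (columns marker_id, x, y).

    Returns marker ids and an ``(n, 2)`` array of (x, y) positions.
    """
    df = pd.read_csv(path)
    missing = {"marker_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"marker file {path} lacks columns: {sorted(missing)}")
    ids = df["marker_id"].astype(int).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"marker file {path} has duplicate marker ids")
    return ids, df[["x", "y"]].to_numpy(dtype=np.float64)


def write_tracks_csv(path: str | Path, tracks: list[MarkerTrack],
                     interval_seconds: float) -> None:
    """Write ``tracks.csv``: one row per (frame, marker), frame-major order."""
    path = Path(path)
    header = ["frame_index", "time_seconds", "marker_id", "x", "y", "cc_max", "status"]
    rows = []
    n_frames = tracks[0].n_frames
    ordered = sorted(tracks, key=lambda t: t.marker_id)
    for f in range(n_frames):
        t_sec = f * interval_seconds
        for tr in ordered:
            rows.append((
                f + 1, float(t_sec), tr.marker_id,
                float(tr.positions[f, 0]), float(tr.positions[f, 1]),
                float(tr.cc_history[f]), tr.status[f],
            ))
    _write_table(path, header, rows)


def read_tracks_csv(path: str | Path) -> tuple[list[MarkerTrack], float]:
    """Rebuild :class:`MarkerTrack` objects from a ``tracks.csv`` file.

    Returns the tracks and the inter-frame interval inferred from the
    ``time_seconds`` column (0 for a single-frame file).
    """
    df = pd.read_csv(path)
    tracks = []
    for mid, grp in df.groupby("marker_id", sort=True):
        grp = grp.sort_values("frame_index")
        tracks.append(MarkerTrack(
            marker_id=int(mid),
            positions=grp[["x", "y"]].to_numpy(dtype=np.float64),
            status=[s if s in (TRACKED, LOST) else TRACKED for s in grp["status"]],
            cc_history=grp["cc_max"].to_numpy(dtype=np.float64),
        ))
    times = np.sort(df["time_seconds"].unique())
    interval = float(times[1] - times[0]) if len(times) > 1 else 0.0
    return tracks, interval


def write_growth_csv(path: str | Path, series: GrowthSeries) -> None:
    """Write ``growth.csv`` from a :class:`GrowthSeries`."""
    df = series.to_frame()
    header = list(df.columns)
    rows = (
        (int(r.frame_index), float(r.time_seconds), float(r.area),
         float(r.rgr_percent_per_frame), float(r.rgr_percent_per_hour),
         bool(r.excluded_flag))
        for r in df.itertuples(index=False)
    )
    _write_table(Path(path), header, rows)
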