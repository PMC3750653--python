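"""Batch pipeline: read frames and markers, track, derive growth, write CSVs.

:class:`RunConfig` mirrors the shell interface one to one; its defaults are
the standard acquisition settings (23x23 template, search length 6,
correlation threshold 0.7, 90 s interval).
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import io as ltio
from .growth import growth_series
from .sequence import read_sequence
from .tracking import track_markers

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "STATUS_SUCCESS", "STATUS_PARTIAL", "STATUS_FAILURE"]

logger = logging.getLogger(__name__)

STATUS_SUCCESS = "success"
STATUS_PARTIAL = "partial"
STATUS_FAILURE = "failure"
_EXIT = {STATUS_SUCCESS: 0, STATUS_PARTIAL: 1, STATUS_FAILURE: 2}


@dataclass
class RunConfig:
    input_dir: str
    marker_file: str
    output_dir: str
    template_size: int = 23
    search_length: int = 6
    cc_threshold: float = 0.7
    interval_seconds: float = 90.0
    smoothing_window: int | None = None
    scale_mm_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.template_size % 2 == 0 or self.template_size < 3:
            raise ValueError(f"template_size must be odd and >= 3, got {self.template_size}")
        if self.search_length < 1:
            raise ValueError(f"search_length must be >= 1, got {self.search_length}")
        if self.interval_seconds <= 0:
            raise ValueError("interval_seconds must be > 0")
        if self.smoothing_window is not None and self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value YAML config; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a flat mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    status: str
    exit_code: int
    tracks_csv: Path
    growth_csv: Path
    log_file: Path
    n_frames: int
    n_markers: int
    lost_events: list[dict]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run track -> area -> RGR on a directory of frames.

    Writes ``tracks.csv``, ``growth.csv`` and a JSON run log to
    ``config.output_dir``. The result status is ``partial`` when any marker
    was lost in any frame (outputs are still written, with flags) and
    ``success`` otherwise.
    """
    t0 = time.monotonic()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []

    seq = read_sequence(config.input_dir, interval_seconds=config.interval_seconds)
    marker_ids, positions = ltio.read_markers(config.marker_file)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        tracks = track_markers(
            seq, positions,
            template_size=config.template_size,
            search_length=config.search_length,
            cc_threshold=config.cc_threshold,
            marker_ids=marker_ids,
        )
        series = growth_series(
            tracks, config.interval_seconds,
            smoothing_window=config.smoothing_window,
            scale_mm_per_px=config.scale_mm_per_px,
        )
        collected.extend(str(w.message) for w in caught)

    tracks_csv = out_dir / "tracks.csv"
    growth_csv = out_dir / "growth.csv"
    ltio.write_tracks_csv(tracks_csv, tracks, config.interval_seconds)
    ltio.write_growth_csv(growth_csv, series)

    lost_events = [
        {"marker_id": tr.marker_id, "frames": [int(f) for f in tr.lost_frames()]}
        for tr in tracks if len(tr.lost_frames())
    ]
    status = STATUS_PARTIAL if lost_events else STATUS_SUCCESS

    log_file = out_dir / "run_log.json"
    log = {
        "parameters": asdict(config),
        "n_frames": seq.n_frames,
        "n_markers": len(tracks),
        "frame_files": seq.filenames,
        "warnings": collected,
        "lost_marker_events": lost_events,
        "status": status,
        "runtime_seconds": round(time.monotonic() - t0, 3),
    }
    log_file.write_text(json.dumps(log, indent=2) + "\n", encoding="utf-8")
    logger.info("pipeline finished with status %s in %.1f s", status,
                log["runtime_seconds"])
    return PipelineResult(
        status=status, exit_code=_EXIT[status],
        tracks_csv=tracks_csv, growth_csv=growth_csv, log_file=log_file,
        n_frames=seq.n_frames, n_markers=len(tracks), lost_events=lost_events,
    )
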