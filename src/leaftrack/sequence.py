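"""Frame sequences: the in-memory time-lapse container and disk round-trip.

A :class:`FrameSequence` holds an ordered stack of single-channel frames
together with the (constant) inter-frame interval. Frames are stored as a
single ``(F, H, W)`` float32 array with intensities on a ``[0, 1]`` scale;
integer images are normalized by the full range of their bit depth on read
so that relative intensities are preserved (no histogram operations, which
would break the affine gray-value invariance of the correlation tracker).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["FrameSequence", "read_sequence", "write_sequence", "natural_key"]

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class FrameSequence:
    """Ordered grayscale frames with 1-based frame indices.

    Parameters
    ----------
    frames
        Array of shape ``(F, H, W)``; float intensities.
    interval_seconds
        Time between consecutive frames, > 0.
    filenames
        Optional source filenames, one per frame (kept for the run log).
    """

    frames: np.ndarray
    interval_seconds: float
    filenames: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (F, H, W) stack, got shape {self.frames.shape}"
            )
        if self.interval_seconds <= 0:
            raise ValueError(f"interval_seconds must be > 0, got {self.interval_seconds}")
        if self.filenames and len(self.filenames) != len(self.frames):
            raise ValueError("one filename per frame required when filenames are given")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def frame_indices(self) -> np.ndarray:
        """1-based consecutive frame numbers."""
        return np.arange(1, self.n_frames + 1)

    def times_seconds(self) -> np.ndarray:
        """Elapsed time of each frame, ``(frame_index - 1) * interval``."""
        return (self.frame_indices - 1) * float(self.interval_seconds)

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


def natural_key(name: str) -> tuple:
    """Sort key comparing numeric chunks numerically: img2 < img10."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _to_grayscale(img: np.ndarray, name: str) -> np.ndarray:
    if img.ndim == 3:
        # drop an alpha channel before averaging, if present
        if img.shape[2] == 4:
            img = img[:, :, :3]
        logger.info("reducing multi-channel image %s to grayscale by channel mean", name)
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError(f"image {name!r} has unsupported shape {img.shape}")
    return img


def _normalize(img: np.ndarray) -> np.ndarray:
    if np.issubdtype(img.dtype, np.integer):
        scale = np.float32(np.iinfo(img.dtype).max)
        return img.astype(np.float32) / scale
    return img.astype(np.float32)


def read_sequence(input_dir: str | Path, interval_seconds: float = 90.0) -> FrameSequence:
    """Load a directory of PNG/TIFF frames in natural filename order.

    Frames are normalized to float32 in ``[0, 1]`` (integer inputs divided by
    their dtype maximum). Multi-channel images are reduced by channel
    averaging, which is logged.

    Raises
    ------
    ValueError
        If fewer than two frames are found or frame dimensions differ.
    """
    input_dir = Path(input_dir)
    names = sorted(
        (p.name for p in input_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
        key=natural_key,
    )
    if len(names) < 2:
        raise ValueError(
            f"need at least 2 frames in {input_dir}, found {len(names)}"
        )
    frames = []
    for name in names:
        path = input_dir / name
        try:
            img = iio.imread(path)
        except Exception as exc:  # pragma: no cover - backend-dependent message
            raise ValueError(f"could not read image file {path}") from exc
        frames.append(_to_grayscale(_normalize(np.asarray(img)), name).astype(np.float32))
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        offenders = sorted(
            f"{n}: {f.shape}" for n, f in zip(names, frames) if f.shape != frames[0].shape
        )
        raise ValueError("mixed image dimensions: " + "; ".join(offenders))
    logger.info("read %d frames from %s", len(frames), input_dir)
    return FrameSequence(np.stack(frames), interval_seconds, filenames=names)


def write_sequence(seq: FrameSequence, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write frames as 16-bit grayscale PNGs, one per frame.

    Intensities are mapped as ``round(v * 65535)``; a sequence whose frames
    already lie on the 16-bit grid (as the synthetic generator produces)
    round-trips bit-exactly through :func:`read_sequence`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(seq.n_frames)))
    paths = []
    for i in range(seq.n_frames):
        data = np.clip(seq.frames[i], 0.0, 1.0)
        img = np.round(data * 65535.0).astype(np.uint16)
        path = out_dir / f"{prefix}_{i + 1:0{width}d}.png"
        iio.imwrite(path, img)
        paths.append(path)
    return paths
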