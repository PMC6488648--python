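"""Time-stamped image frames and their on-disk layout.

A fixed observatory camera produces one frame per hour; a frame is an RGB
raster plus its timestamp and an optional validity mask (pixels rolled in at
the border during registration are invalid).  Frames are stored as PNG named
by their timestamp in ISO 8601 basic format (``YYYYMMDDTHHMMSS.png``), which
sorts chronologically and avoids characters that are unsafe in filenames.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["ImageFrame", "save_frames", "load_frames"]

_TS_FORMAT = "%Y%m%dT%H%M%S"


@dataclass
class ImageFrame:
    """A time-stamped RGB raster.

    Attributes
    ----------
    timestamp
        Acquisition time (UTC).
    pixels
        ``(H, W, 3)`` uint8 RGB raster.
    valid
        Optional ``(H, W)`` boolean mask of valid pixels; ``None`` means all
        pixels are valid.
    """

    timestamp: pd.Timestamp
    pixels: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp)
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB raster")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("frame dimensions must be positive")
        if self.valid is not None and self.valid.shape != self.pixels.shape[:2]:
            raise ValueError("valid mask must match frame dimensions")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def gray(self) -> np.ndarray:
        """Luma-weighted grayscale view (float in [0, 255])."""
        return self.pixels.astype(float) @ np.array([0.299, 0.587, 0.114])


def save_frames(frames: list[ImageFrame], directory) -> list[Path]:
    """Write frames as ``<ISO8601 timestamp>.png`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames:
        path = directory / (f.timestamp.strftime(_TS_FORMAT) + ".png")
        iio.imwrite(path, f.pixels)
        paths.append(path)
    return paths


def load_frames(directory, pattern: str = "*.png") -> list[ImageFrame]:
    """Read a directory of timestamp-named frames, sorted chronologically."""
    directory = Path(directory)
    frames = []
    for path in sorted(directory.glob(pattern)):
        ts = pd.to_datetime(path.stem, format=_TS_FORMAT)
        frames.append(ImageFrame(ts, np.asarray(iio.imread(path))[..., :3]))
    return frames
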