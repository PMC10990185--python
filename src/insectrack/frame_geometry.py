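"""Low-resolution detection geometry on high-resolution frames.

The detector runs on a 320x320 low-quality (LQ) frame that is a stretched
downscale of the synchronized high-quality (HQ) frame (1920x1080 or
3840x2160), so normalized box coordinates transfer between the two streams
directly: mapping a detection onto the HQ frame is pure scaling. Insect
crops are cut from the HQ frame, and crop capture is throttled per track to
the configured frequency (~1 s by default) so each tracked individual
yields roughly one saved image per second regardless of the pipeline frame
rate.

Pixel rectangles use 0-based, half-open ``[x_min, x_max) x [y_min, y_max)``
convention, with floor/ceil rounding so an insect's pixels are never cut
off at box edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FrameSpec",
    "PixelRect",
    "DegenerateBoxError",
    "lq_to_hq",
    "should_capture",
    "CaptureThrottle",
    "crop",
    "save_crop_jpeg",
    "crop_filename",
]


class DegenerateBoxError(ValueError):
    """Bounding box collapsed to zero area after clipping/rounding."""


@dataclass(frozen=True)
class FrameSpec:
    """Frame dimensions and the physical size of the imaged flower platform."""

    lq_size: tuple[int, int] = (320, 320)
    hq_size: tuple[int, int] = (1920, 1080)
    platform_size_mm: tuple[float, float] = (350.0, 200.0)

    def __post_init__(self):
        for name in ("lq_size", "hq_size", "platform_size_mm"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


PixelRect = tuple[int, int, int, int]


def lq_to_hq(
    bbox: tuple[float, float, float, float], hq_size: tuple[int, int]
) -> PixelRect:
    """Map a normalized detection box to an integer HQ pixel rectangle.

    Coordinates are clipped to the frame, then rounded outward
    (floor on minima, ceil on maxima) in the half-open pixel convention.
    """
    if not all(math.isfinite(v) for v in bbox):
        raise ValueError(f"non-finite bbox {bbox}")
    width, height = hq_size
    x_min = max(0.0, min(1.0, bbox[0]))
    y_min = max(0.0, min(1.0, bbox[1]))
    x_max = max(0.0, min(1.0, bbox[2]))
    y_max = max(0.0, min(1.0, bbox[3]))
    rect = (
        math.floor(x_min * width),
        math.floor(y_min * height),
        math.ceil(x_max * width),
        math.ceil(y_max * height),
    )
    if rect[0] >= rect[2] or rect[1] >= rect[3]:
        raise DegenerateBoxError(f"zero-area box after clipping: {bbox} -> {rect}")
    return rect


def should_capture(
    track_id: int | str,
    timestamp: float,
    capture_state: dict,
    frequency: float = 1.0,
) -> tuple[bool, dict]:
    """Per-track crop throttling: capture at most once per ``frequency`` s.

    True iff the track was never captured or at least ``frequency`` seconds
    have elapsed since its last capture. Pure: returns a new state dict,
    updated only when the answer is True.
    """
    if frequency <= 0:
        raise ValueError("capture frequency must be > 0")
    last = capture_state.get(track_id)
    if last is not None and timestamp - last < frequency:
        return False, capture_state
    new_state = dict(capture_state)
    new_state[track_id] = timestamp
    return True, new_state


class CaptureThrottle:
    """Mutable wrapper over :func:`should_capture` for pipeline loops."""

    def __init__(self, frequency: float = 1.0):
        if frequency <= 0:
            raise ValueError("capture frequency must be > 0")
        self.frequency = frequency
        self._last: dict = {}

    def should_capture(self, track_id: int | str, timestamp: float) -> bool:
        ok, self._last = should_capture(track_id, timestamp, self._last, self.frequency)
        return ok


def crop(frame: np.ndarray, rect: PixelRect) -> np.ndarray:
    """Extract the pixel rectangle from an HQ frame array (H x W [x C])."""
    x_min, y_min, x_max, y_max = rect
    height, width = frame.shape[:2]
    if x_min < 0 or y_min < 0 or x_max > width or y_max > height:
        raise ValueError(f"rect {rect} outside frame bounds {(width, height)}")
    if x_min >= x_max or y_min >= y_max:
        raise DegenerateBoxError(f"empty rect {rect}")
    return frame[y_min:y_max, x_min:x_max].copy()


def crop_filename(recording_id: str, track_id: int, timestamp: float) -> str:
    """Relative crop path recorded in the metadata ``crop_path`` column."""
    return f"{recording_id}/{track_id}/{timestamp:.3f}.jpg"


def save_crop_jpeg(image: np.ndarray, path: str | Path) -> Path:
    """Write a crop as JPEG (uint8 array expected)."""
    from PIL import Image

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path, format="JPEG")
    return path
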