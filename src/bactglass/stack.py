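"""Image-stack container and TIFF I/O.

The whole pipeline operates on time-lapse grayscale movies carried as an
:class:`ImageStack`: a ``(T, H, W)`` intensity array plus the two physical
scales every downstream quantity needs, the pixel size (μm/px) and the frame
interval (s).

Coordinate convention (shared by all modules): pixel ``(row 0, col 0)`` is the
top-left corner, ``x`` increases rightward along columns, ``y`` increases
downward along rows, and pixel centers sit at half-integer pixel coordinates.
Angles are measured from the +x axis, counterclockwise in the physical
(y-up) frame, so an angle ``a`` maps to direction ``(cos a, -sin a)`` in
(col, row) increments.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Time-lapse grayscale movie with physical scales attached.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity frames, any numeric dtype / scale.
    pixel_size : float
        Pixel size in μm per pixel (square pixels).
    frame_interval : float
        Time between consecutive frames in seconds.
    roi : tuple or None
        ``(x, y, w, h)`` crop applied to obtain this stack, in pixel
        coordinates of the original frame; ``None`` for an uncropped stack.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    roi: tuple[int, int, int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (T, H, W), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def astype(self, dtype) -> "ImageStack":
        return replace(self, frames=self.frames.astype(dtype))

    def __getitem__(self, t) -> np.ndarray:
        return self.frames[t]


def read_stack(path: str, pixel_size: float, frame_interval: float) -> ImageStack:
    """Read a movie from a multi-page TIFF or a directory of frame images.

    ``path`` may be a single TIFF file, a directory (frames sorted by name),
    or a glob pattern. Physical scales are not stored in plain TIFFs, so they
    are supplied by the caller (typically from the run config or a JSON
    sidecar written by :func:`write_stack`).
    """
    if os.path.isdir(path):
        files = sorted(
            glob.glob(os.path.join(path, "*.tif"))
            + glob.glob(os.path.join(path, "*.tiff"))
            + glob.glob(os.path.join(path, "*.png"))
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG frames in directory {path!r}")
        frames = np.stack([tifffile.imread(f) if f.endswith((".tif", ".tiff"))
                           else _read_png(f) for f in files])
    elif any(ch in path for ch in "*?["):
        files = sorted(glob.glob(path))
        if not files:
            raise FileNotFoundError(f"glob {path!r} matched no files")
        frames = np.stack([tifffile.imread(f) for f in files])
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    return ImageStack(frames, pixel_size, frame_interval)


def _read_png(path: str) -> np.ndarray:
    from imageio import v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    return img


def write_stack(stack: ImageStack, path: str, sidecar: bool = True) -> None:
    """Write a stack as a multi-page TIFF plus a JSON sidecar of its scales."""
    frames = stack.frames
    if frames.dtype.kind == "f":
        # Store float stacks as 32-bit TIFF; integer stacks pass through.
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames)
    if sidecar:
        meta = {
            "pixel_size_um": stack.pixel_size,
            "frame_interval_s": stack.frame_interval,
            "roi": list(stack.roi) if stack.roi is not None else None,
            **{k: v for k, v in stack.meta.items() if _json_ok(v)},
        }
        with open(os.path.splitext(path)[0] + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def _json_ok(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
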