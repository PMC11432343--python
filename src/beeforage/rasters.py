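"""Raster boundary: reading/writing frames and HSV scale conversion.

Everything downstream of this module works on uint8 HSV arrays with all
three channels on a 0-255 scale and a hue period of 256 (so the printed
threshold triplets apply directly).  Conversions to and from RGB files
happen only here.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Tuple

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image

from beeforage.errors import ParameterError, ScaleMismatchError

__all__ = [
    "rgb_to_internal_hsv",
    "internal_hsv_to_rgb",
    "read_frame_hsv",
    "write_frame_hsv",
    "list_frames",
    "check_internal_scale",
]

HUE_PERIOD = 256


def check_internal_scale(hsv: np.ndarray) -> np.ndarray:
    """Validate an internal-scale HSV raster (H,W,3 uint-like, 0-255)."""
    arr = np.asarray(hsv)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ScaleMismatchError(f"expected (H, W, 3) raster, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ScaleMismatchError("channel values outside the internal 0-255 scale")
    return arr


def rgb_to_internal_hsv(rgb: np.ndarray) -> np.ndarray:
    """uint8 RGB -> uint8 HSV on the internal 0-255 scale (hue period 256)."""
    rgb = np.asarray(rgb)
    if rgb.dtype != np.uint8:
        raise ParameterError("expected a uint8 RGB raster")
    hsv = rgb_to_hsv(rgb.astype(np.float64) / 255.0)
    out = np.empty_like(rgb)
    out[..., 0] = np.round(hsv[..., 0] * HUE_PERIOD).astype(np.int64) % HUE_PERIOD
    out[..., 1] = np.round(hsv[..., 1] * 255.0).astype(np.uint8)
    out[..., 2] = np.round(hsv[..., 2] * 255.0).astype(np.uint8)
    return out


def internal_hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Internal-scale HSV -> uint8 RGB."""
    arr = check_internal_scale(hsv).astype(np.float64)
    stacked = np.stack(
        [arr[..., 0] / HUE_PERIOD, arr[..., 1] / 255.0, arr[..., 2] / 255.0], axis=-1
    )
    return np.round(hsv_to_rgb(stacked) * 255.0).astype(np.uint8)


def read_frame_hsv(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG frame and convert to internal-scale HSV."""
    with Image.open(path) as img:
        rgb = np.asarray(img.convert("RGB"))
    return rgb_to_internal_hsv(rgb)


def write_frame_hsv(path: str | Path, hsv: np.ndarray) -> None:
    """Write an internal-scale HSV raster as an RGB image file."""
    Image.fromarray(internal_hsv_to_rgb(hsv)).save(path)


def list_frames(directory: str | Path, pattern: str = "*.png") -> List[Tuple[int, Path]]:
    """Numbered frame files, sorted by the frame index parsed from the name."""
    from beeforage.detections import frame_index_from_name

    frames = [
        (frame_index_from_name(p.name), p) for p in Path(directory).glob(pattern)
    ]
    frames.sort(key=lambda item: item[0])
    return frames
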