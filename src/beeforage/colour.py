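"""Flower-colour segmentation, cover estimation, optimal flower colour, heatmaps.

All rasters are internal-scale HSV (three uint8 channels on 0-255, hue
period 256); the printed per-species threshold triplets apply directly.
A band channel whose lower bound exceeds its upper bound is treated as an
inverted pass band: a value passes iff it is >= lower OR <= upper.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from beeforage.detections import DetectionSet
from beeforage.errors import (
    EmptyRegionError,
    NoFlowerPixelsError,
    ParameterError,
)
from beeforage.geometry import Rect
from beeforage.rasters import HUE_PERIOD, check_internal_scale

logger = logging.getLogger(__name__)

__all__ = [
    "ColourBand",
    "OFC",
    "Heatmap",
    "DEFAULT_BANDS",
    "band_mask",
    "flower_cover",
    "compute_ofc",
    "circular_colour_distance",
    "build_heatmap",
    "deviation_histogram",
    "load_colour_config",
    "save_colour_config",
]

Triplet = Tuple[int, int, int]
CHANNEL_NAMES = ("hue", "saturation", "value")


@dataclass(frozen=True)
class ColourBand:
    """Per-species lower/upper HSB thresholds with wrap semantics.

    ``inverted_channels`` marks channels whose pass band is the complement
    of [lower, upper]; by default any channel with lower > upper is
    inverted.
    """

    lower: Triplet
    upper: Triplet
    species: str = ""
    inverted_channels: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        for triplet in (self.lower, self.upper):
            if len(triplet) != 3 or any(not 0 <= v <= 255 for v in triplet):
                raise ParameterError(f"band triplet {triplet} outside 0-255")
        if self.inverted_channels is None:
            inv = tuple(
                c for c in range(3) if self.lower[c] > self.upper[c]
            )
            object.__setattr__(self, "inverted_channels", inv)
        else:
            object.__setattr__(self, "inverted_channels", tuple(self.inverted_channels))
            for c in range(3):
                if self.lower[c] > self.upper[c] and c not in self.inverted_channels:
                    raise ParameterError(
                        f"channel {CHANNEL_NAMES[c]} has lower > upper but is not inverted"
                    )

    def channel_passes(self, channel: int, value: np.ndarray) -> np.ndarray:
        lo, hi = self.lower[channel], self.upper[channel]
        if channel in self.inverted_channels:
            return (value >= lo) | (value <= hi)
        return (value >= lo) & (value <= hi)


#: Printed per-species HSB threshold triplets (lower; upper).
DEFAULT_BANDS: Dict[str, ColourBand] = {
    "lotus": ColourBand((11, 42, 120), (255, 160, 255), species="lotus"),
    "persicaria": ColourBand((140, 255, 0), (140, 40, 255), species="persicaria"),
    "trifolium": ColourBand((85, 255, 0), (247, 186, 255), species="trifolium"),
}

#: The per-species "optimal flower colour": median in-band HSV triplet.
OFC = Tuple[float, float, float]


def band_mask(image_hsv: np.ndarray, band: ColourBand) -> np.ndarray:
    """Boolean mask of pixels passing every channel test of the band."""
    arr = check_internal_scale(image_hsv)
    mask = np.ones(arr.shape[:2], dtype=bool)
    for c in range(3):
        mask &= band.channel_passes(c, arr[..., c])
    return mask


def _rect_slices(rect: Rect) -> Tuple[slice, slice]:
    return (slice(int(rect.y1), int(rect.y2)), slice(int(rect.x1), int(rect.x2)))


def flower_cover(frame: np.ndarray, band: ColourBand, rect: Rect) -> float:
    """Fraction of quadrat pixels passing the species colour band."""
    arr = check_internal_scale(frame)
    ys, xs = _rect_slices(rect)
    if rect.x1 < 0 or rect.y1 < 0 or rect.x2 > arr.shape[1] or rect.y2 > arr.shape[0]:
        raise ParameterError(f"quadrat {rect} outside frame of shape {arr.shape[:2]}")
    region = arr[ys, xs]
    n_pixels = region.shape[0] * region.shape[1]
    if n_pixels == 0:
        raise ParameterError("empty quadrat rectangle")
    return float(band_mask(region, band).sum()) / n_pixels


def _pool_in_band_pixels(
    frames: Sequence[np.ndarray], band: ColourBand
) -> np.ndarray:
    pooled: List[np.ndarray] = []
    for frame in frames:
        arr = check_internal_scale(frame)
        mask = band_mask(arr, band)
        if mask.any():
            pooled.append(arr[mask])
    if not pooled:
        raise NoFlowerPixelsError("no in-band pixels in the sampled frames")
    return np.concatenate(pooled, axis=0)


def compute_ofc(
    frames: Sequence[np.ndarray],
    band: ColourBand,
    n_frames: int = 10,
    seed: Optional[int] = None,
) -> OFC:
    """Channel-wise median colour of in-band pixels pooled over sampled frames.

    ``n_frames`` frames are sampled without replacement (all frames when
    fewer are available); deterministic given ``seed``.  The median uses
    the nearest-observed-value convention so each channel of the result
    is an actual in-band pixel value and the OFC passes its own band.
    """
    if not frames:
        raise ParameterError("no frames supplied")
    rng = np.random.default_rng(seed)
    k = min(n_frames, len(frames))
    idx = rng.choice(len(frames), size=k, replace=False)
    pixels = _pool_in_band_pixels([frames[i] for i in sorted(idx)], band)
    med = np.quantile(pixels.astype(np.float64), 0.5, axis=0, method="nearest")
    return (float(med[0]), float(med[1]), float(med[2]))


def circular_colour_distance(
    pixel_hsv: Union[Sequence[float], np.ndarray],
    ofc: OFC,
    h_period: int = HUE_PERIOD,
) -> Union[float, np.ndarray]:
    """Euclidean HSV distance with the hue difference wrapped on its circle.

    Accepts a single (h, s, v) triplet or an (..., 3) array; returns a
    scalar or an array of matching leading shape.
    """
    arr = np.asarray(pixel_hsv, dtype=np.float64)
    scalar = arr.ndim == 1
    dh = np.abs(arr[..., 0] - ofc[0])
    dh = np.minimum(dh, h_period - dh)
    ds = arr[..., 1] - ofc[1]
    dv = arr[..., 2] - ofc[2]
    dist = np.sqrt(dh * dh + ds * ds + dv * dv)
    return float(dist) if scalar else dist


@dataclass
class Heatmap:
    """Per-pixel mean colour distance from the OFC, with contribution counts.

    Pixels that were under a bounding box in every sampled frame have
    count 0 and an undefined (NaN) mean.
    """

    mean: np.ndarray
    counts: np.ndarray
    ofc: OFC
    seed: Optional[int] = None
    sampled_frames: Tuple[int, ...] = field(default_factory=tuple)

    @property
    def defined(self) -> np.ndarray:
        return self.counts > 0

    def values(self) -> np.ndarray:
        """Defined distances as a flat array."""
        return self.mean[self.defined]


def build_heatmap(
    frames: Sequence[np.ndarray],
    dets: DetectionSet,
    ofc: OFC,
    n_frames: int = 3000,
    seed: Optional[int] = None,
) -> Heatmap:
    """Mean per-pixel distance from the OFC over sampled frames.

    At each sampled frame, the pixels under that frame's bounding boxes
    are excluded from the average.  Frame list indices are sampled
    without replacement; when fewer than ``n_frames`` frames exist, all
    are used and a notice is logged.
    """
    if not frames:
        raise ParameterError("no frames supplied")
    rng = np.random.default_rng(seed)
    if n_frames >= len(frames):
        if n_frames > len(frames):
            logger.info(
                "requested %d frames but only %d available; using all", n_frames, len(frames)
            )
        idx = np.arange(len(frames))
    else:
        idx = np.sort(rng.choice(len(frames), size=n_frames, replace=False))

    shape = check_internal_scale(frames[0]).shape[:2]
    total = np.zeros(shape, dtype=np.float64)
    counts = np.zeros(shape, dtype=np.int64)
    by_frame = dets.by_frame()
    for i in idx:
        arr = check_internal_scale(frames[i])
        if arr.shape[:2] != shape:
            raise ParameterError("frames have inconsistent shapes")
        include = np.ones(shape, dtype=bool)
        for det in by_frame.get(int(i), []):
            ys, xs = _rect_slices(det.box)
            include[ys, xs] = False
        dist = circular_colour_distance(arr, ofc)
        total[include] += dist[include]
        counts += include

    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return Heatmap(mean=mean, counts=counts, ofc=ofc, seed=seed,
                   sampled_frames=tuple(int(i) for i in idx))


def deviation_histogram(
    heatmap: Heatmap,
    region: Union[str, np.ndarray] = "all",
    n_points: int = 100_000,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Random sample of defined heatmap distances for histogramming.

    ``region`` is ``"all"`` or a boolean mask (e.g. pixels under bounding
    boxes).  Samples ``min(n_points, available)`` defined pixels uniformly
    without replacement; deterministic given ``seed``.
    """
    if isinstance(region, str):
        if region != "all":
            raise ParameterError(f"unknown region {region!r}; pass 'all' or a mask")
        mask = heatmap.defined
    else:
        mask = np.asarray(region, dtype=bool) & heatmap.defined
    values = heatmap.mean[mask]
    if values.size == 0:
        raise EmptyRegionError("region contains no defined heatmap pixels")
    rng = np.random.default_rng(seed)
    k = min(n_points, values.size)
    idx = rng.choice(values.size, size=k, replace=False)
    return values[idx]


# ---------------------------------------------------------------------------
# Colour-config I/O
# ---------------------------------------------------------------------------

def load_colour_config(path: str | Path, species: Optional[str] = None) -> ColourBand:
    """Read a colour band from YAML/JSON.

    The file is either a single band mapping (``lower``, ``upper``,
    optional ``inverted_channels``/``species``) or a mapping of species
    name to band, in which case ``species`` selects the entry.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if "lower" not in data:
        if species is None:
            raise ParameterError("multi-species config requires a species name")
        if species not in data:
            raise ParameterError(f"species {species!r} not in config {sorted(data)}")
        data = data[species]
        data.setdefault("species", species)
    inv = data.get("inverted_channels")
    return ColourBand(
        lower=tuple(data["lower"]),
        upper=tuple(data["upper"]),
        species=data.get("species", species or ""),
        inverted_channels=tuple(inv) if inv is not None else None,
    )


def save_colour_config(band: ColourBand, path: str | Path) -> None:
    path = Path(path)
    data = {
        "species": band.species,
        "lower": list(band.lower),
        "upper": list(band.upper),
        "inverted_channels": list(band.inverted_channels or ()),
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
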