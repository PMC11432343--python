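"""Per-video behavioural statistics from counts, colour masks and detections.

Three headline quantities per video:

* attractiveness — total detections divided by total frames (bee-free
  frames included);
* carrying capacity — mean simultaneous count conditioned on presence
  (detections / frames-with-bees), standardised by percent flower cover;
* on-flower time proportion — share of detection-frames in which the box
  region is at least 20% flower-coloured in a bee-free reference frame.

Undefined metrics (e.g. no frames with bees) are reported as NaN, never
as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from beeforage.colour import ColourBand, band_mask, flower_cover
from beeforage.detections import Detection, DetectionSet, counts_per_frame
from beeforage.errors import ParameterError
from beeforage.geometry import Rect
from beeforage.rasters import check_internal_scale

__all__ = [
    "OnFlowerCall",
    "VideoMetrics",
    "attractiveness",
    "carrying_capacity",
    "find_reference_frame",
    "classify_on_flower",
    "classify_all",
    "time_budget",
    "simultaneity_stats",
    "summarise_video",
    "metrics_table",
    "total_frames",
    "ON_FLOWER_THRESHOLD",
]

#: Minimum flower-pixel fraction inside a box for an on-flower call (inclusive).
ON_FLOWER_THRESHOLD = 0.20


def attractiveness(counts: Sequence[int]) -> float:
    """Total detections per frame, bee-free frames included."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ParameterError("empty count vector")
    return float(counts.sum()) / counts.size


def carrying_capacity(counts: Sequence[int], cover_pct: float) -> float:
    """Mean count over frames with bees, divided by percent flower cover.

    Returns NaN (metric undefined, reported as missing) when no frame
    contains a bee.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ParameterError("empty count vector")
    if cover_pct <= 0:
        raise ParameterError("cover_pct must be positive")
    bee_frames = int((counts > 0).sum())
    if bee_frames == 0:
        return math.nan
    return (float(counts.sum()) / bee_frames) / cover_pct


def simultaneity_stats(counts: Sequence[int]) -> Tuple[int, float]:
    """(max simultaneous count, mean count over frames with at least one bee).

    The mean is NaN when no frame has a bee.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ParameterError("empty count vector")
    present = counts[counts > 0]
    mean = float(present.mean()) if present.size else math.nan
    return int(counts.max()), mean


@dataclass(frozen=True)
class OnFlowerCall:
    """On-flower classification of one detection against a bee-free reference frame."""

    detection: Detection
    flower_pixel_fraction: Optional[float]
    on_flower: Optional[bool]
    reference_frame_idx: Optional[int]

    @property
    def resolved(self) -> bool:
        return self.reference_frame_idx is not None


def find_reference_frame(
    det: Detection,
    dets: DetectionSet,
    n_frames: int,
    window: Optional[int] = None,
) -> Optional[int]:
    """Nearest frame in which no detection box intersects the query box.

    Frames are searched in order of temporal distance from the detection,
    the earlier frame preferred on ties; ``window`` bounds the search to
    ``|t - frame_idx| <= window`` (default: the whole video).
    """
    by_frame = dets.by_frame()
    max_offset = n_frames if window is None else window
    for offset in range(0, max_offset + 1):
        for t in ((det.frame_idx - offset, det.frame_idx + offset)
                  if offset else (det.frame_idx,)):
            if not 0 <= t < n_frames:
                continue
            if any(d.box.intersects(det.box) for d in by_frame.get(t, [])):
                continue
            return t
    return None


def classify_on_flower(
    det: Detection,
    frames: Sequence[np.ndarray],
    dets: DetectionSet,
    band: ColourBand,
    threshold: float = ON_FLOWER_THRESHOLD,
    window: Optional[int] = None,
) -> OnFlowerCall:
    """Is this detection on a flower?

    The box region is masked with the species colour band in the nearest
    bee-free reference frame; the call is on-flower iff the flower-pixel
    fraction reaches ``threshold`` (inclusive).  When no reference frame
    exists within the window the call is unresolved.
    """
    ref = find_reference_frame(det, dets, n_frames=len(frames), window=window)
    if ref is None:
        return OnFlowerCall(det, None, None, None)
    arr = check_internal_scale(frames[ref])
    ys = slice(max(int(det.box.y1), 0), min(int(det.box.y2), arr.shape[0]))
    xs = slice(max(int(det.box.x1), 0), min(int(det.box.x2), arr.shape[1]))
    region = arr[ys, xs]
    n_pixels = region.shape[0] * region.shape[1]
    if n_pixels == 0:
        return OnFlowerCall(det, None, None, None)
    fraction = float(band_mask(region, band).sum()) / n_pixels
    return OnFlowerCall(det, fraction, fraction >= threshold, ref)


def classify_all(
    frames: Sequence[np.ndarray],
    dets: DetectionSet,
    band: ColourBand,
    threshold: float = ON_FLOWER_THRESHOLD,
    window: Optional[int] = None,
) -> List[OnFlowerCall]:
    return [
        classify_on_flower(det, frames, dets, band, threshold=threshold, window=window)
        for det in dets
    ]


def time_budget(calls: Sequence[OnFlowerCall]) -> Tuple[float, float]:
    """(percent on-flower, percent off-flower) over resolved calls.

    Unresolved calls are excluded; with zero resolved calls both
    percentages are NaN.
    """
    resolved = [c for c in calls if c.resolved]
    if not resolved:
        return (math.nan, math.nan)
    pct_on = 100.0 * sum(1 for c in resolved if c.on_flower) / len(resolved)
    return (pct_on, 100.0 - pct_on)


@dataclass
class VideoMetrics:
    """One row of the per-video metrics table."""

    video_id: str
    species: str
    n_frames: int
    total_detections: int
    frames_with_bees: int
    attractiveness: float
    carrying_capacity: float
    flower_cover_pct: float
    pct_time_on_flower: float
    pct_time_off_flower: float
    max_simultaneous: int
    mean_simultaneous: float
    n_unresolved_calls: int = 0
    seed: Optional[int] = None
    extra: Dict[str, object] = field(default_factory=dict)


def summarise_video(
    video_id: str,
    species: str,
    frames: Sequence[np.ndarray],
    dets: DetectionSet,
    band: ColourBand,
    quadrat: Rect,
    seed: Optional[int] = None,
    on_flower_threshold: float = ON_FLOWER_THRESHOLD,
    window: Optional[int] = None,
) -> Tuple[VideoMetrics, List[OnFlowerCall]]:
    """Compute all per-video metrics from fully post-processed detections.

    Flower cover is estimated from one random frame (seed-controlled),
    expressed as a percentage for the carrying-capacity standardisation.
    """
    n_frames = len(frames)
    counts = counts_per_frame(dets, n_frames)
    rng = np.random.default_rng(seed)
    cover_frame = int(rng.integers(n_frames))
    cover_pct = 100.0 * flower_cover(frames[cover_frame], band, quadrat)

    calls = classify_all(frames, dets, band, threshold=on_flower_threshold, window=window)
    pct_on, pct_off = time_budget(calls)
    max_sim, mean_sim = simultaneity_stats(counts)
    cc = carrying_capacity(counts, cover_pct) if cover_pct > 0 else math.nan

    metrics = VideoMetrics(
        video_id=video_id,
        species=species,
        n_frames=n_frames,
        total_detections=int(counts.sum()),
        frames_with_bees=int((counts > 0).sum()),
        attractiveness=attractiveness(counts),
        carrying_capacity=cc,
        flower_cover_pct=cover_pct,
        pct_time_on_flower=pct_on,
        pct_time_off_flower=pct_off,
        max_simultaneous=max_sim,
        mean_simultaneous=mean_sim,
        n_unresolved_calls=sum(1 for c in calls if not c.resolved),
        seed=seed,
        extra={"cover_frame_idx": cover_frame, "on_flower_threshold": on_flower_threshold},
    )
    return metrics, calls


_TABLE_COLUMNS = [
    "video_id", "species", "n_frames", "total_detections", "frames_with_bees",
    "attractiveness", "carrying_capacity", "flower_cover_pct",
    "pct_time_on_flower", "pct_time_off_flower",
    "max_simultaneous", "mean_simultaneous", "n_unresolved_calls", "seed",
]


def metrics_table(metrics: Sequence[VideoMetrics]) -> pd.DataFrame:
    """Per-video metrics as a DataFrame (one row per video)."""
    rows = [{col: getattr(m, col) for col in _TABLE_COLUMNS} for m in metrics]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def total_frames(table: pd.DataFrame, column: str = "n_frames") -> int:
    """Total analysed frames across a metrics table."""
    if column not in table.columns:
        raise ParameterError(f"column {column!r} not in table")
    return int(table[column].sum())
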