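"""Post-processing of raw tiled detector output into per-frame counts.

The stages mirror the order in which they are applied to field video:
confidence filtering (inclusive threshold), duplicate-box merging by
centroid distance (transitive closure), quadrat clipping by box centroid,
and F1 evaluation against manual annotations.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from beeforage.errors import ParameterError
from beeforage.geometry import Rect, centroid_in_quadrat

__all__ = [
    "Detection",
    "DetectionSet",
    "MatchResult",
    "filter_confidence",
    "merge_boxes",
    "merge_all",
    "clip_to_quadrat",
    "match_and_score",
    "counts_per_frame",
    "default_merge_dist_px",
    "DEFAULT_CONFIDENCE",
    "read_detections_csv",
    "write_detections_csv",
    "read_yolo_frame",
    "read_yolo_dir",
]

#: Per-species confidence thresholds used for box filtering.
DEFAULT_CONFIDENCE = {"trifolium": 0.7, "lotus": 0.8, "persicaria": 0.8}

#: Average bumblebee body length; half of it sets the merge distance.
BEE_BODY_MM = 30.0


@dataclass(frozen=True)
class Detection:
    """One bounding box emitted by the detector (or by merging)."""

    frame_idx: int
    box: Rect
    confidence: float
    label: str = "bumblebee"
    source: str = "raw"

    def __post_init__(self) -> None:
        if self.frame_idx < 0:
            raise ParameterError("frame_idx must be non-negative")
        if not 0.0 <= self.confidence <= 1.0:
            raise ParameterError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class DetectionSet:
    """Detections grouped by frame, with provenance metadata.

    Insertion order is preserved within each frame.
    """

    detections: List[Detection] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self) -> Iterator[Detection]:
        return iter(self.detections)

    def by_frame(self) -> Dict[int, List[Detection]]:
        groups: Dict[int, List[Detection]] = {}
        for det in self.detections:
            groups.setdefault(det.frame_idx, []).append(det)
        return groups

    def frame_indices(self) -> List[int]:
        return sorted({d.frame_idx for d in self.detections})

    def with_detections(self, detections: Sequence[Detection], **meta) -> "DetectionSet":
        return DetectionSet(detections=list(detections), metadata={**self.metadata, **meta})


def default_merge_dist_px(mm_per_px: float, half_body_mm: float = BEE_BODY_MM / 2) -> float:
    """Merge distance in pixels: half an average bumblebee body."""
    if mm_per_px <= 0:
        raise ParameterError("mm_per_px must be positive")
    return half_body_mm / mm_per_px


def filter_confidence(dets: DetectionSet, threshold: float) -> DetectionSet:
    """Keep detections with confidence >= threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold {threshold} outside [0, 1]")
    kept = [d for d in dets if d.confidence >= threshold]
    return dets.with_detections(kept, confidence_threshold=threshold)


def merge_boxes(frame_dets: Sequence[Detection], merge_dist_px: float) -> List[Detection]:
    """Merge duplicate boxes within one frame by centroid proximity.

    Connected components under "centroid distance <= merge_dist_px" are each
    replaced by a single detection: union hull of the member boxes,
    maximum member confidence, source ``"merged"``.  The result is
    independent of input order (components sorted by top-left corner).
    """
    if merge_dist_px <= 0:
        raise ParameterError("merge_dist_px must be positive")
    if not frame_dets:
        return []
    frames = {d.frame_idx for d in frame_dets}
    if len(frames) > 1:
        raise ParameterError(f"merge_boxes expects a single frame, got {sorted(frames)}")

    centroids = np.array([d.box.centroid for d in frame_dets])
    adj = cdist(centroids, centroids) <= merge_dist_px
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    merged: List[Detection] = []
    for comp in range(n_comp):
        members = [frame_dets[i] for i in np.flatnonzero(labels == comp)]
        box = Rect(
            min(m.box.x1 for m in members),
            min(m.box.y1 for m in members),
            max(m.box.x2 for m in members),
            max(m.box.y2 for m in members),
        )
        merged.append(
            Detection(
                frame_idx=members[0].frame_idx,
                box=box,
                confidence=max(m.confidence for m in members),
                label=members[0].label,
                source="merged",
            )
        )
    merged.sort(key=lambda d: (d.box.y1, d.box.x1, d.box.y2, d.box.x2))
    return merged


def merge_all(dets: DetectionSet, merge_dist_px: float) -> DetectionSet:
    """Apply :func:`merge_boxes` frame by frame across a whole set."""
    out: List[Detection] = []
    for frame_idx in sorted(dets.by_frame()):
        out.extend(merge_boxes(dets.by_frame()[frame_idx], merge_dist_px))
    return dets.with_detections(out, merge_dist_px=merge_dist_px)


def clip_to_quadrat(dets: DetectionSet, rect: Rect) -> DetectionSet:
    """Keep detections whose box centroid falls inside the quadrat.

    Boxes are kept whole, never cropped to the rectangle.
    """
    kept = [d for d in dets if centroid_in_quadrat(d.box, rect)]
    return dets.with_detections(kept, quadrat=rect.as_tuple())


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching predictions against manual annotations."""

    tp: int
    fp: int
    fn: int
    pairs: Tuple[Tuple[int, int], ...] = ()

    @property
    def f1(self) -> float:
        if self.tp + self.fp + self.fn == 0:
            return 1.0  # nothing to detect and nothing detected
        return 2 * self.tp / (2 * self.tp + self.fp + self.fn)


def match_and_score(
    pred: Sequence[Detection],
    truth: Sequence[Detection],
    match_dist_px: float,
) -> MatchResult:
    """One-to-one greedy matching by ascending centroid distance.

    A (pred, truth) pair matches iff their centroid distance is at most
    ``match_dist_px``; each box is used at most once.
    """
    if match_dist_px <= 0:
        raise ParameterError("match_dist_px must be positive")
    if not pred or not truth:
        return MatchResult(tp=0, fp=len(pred), fn=len(truth))

    pc = np.array([d.box.centroid for d in pred])
    tc = np.array([d.box.centroid for d in truth])
    dist = cdist(pc, tc)
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]

    used_p: set = set()
    used_t: set = set()
    pairs: List[Tuple[int, int]] = []
    for i, j in order:
        if dist[i, j] > match_dist_px:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(int(i))
        used_t.add(int(j))
        pairs.append((int(i), int(j)))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(pred) - tp, fn=len(truth) - tp, pairs=tuple(pairs))


def counts_per_frame(dets: DetectionSet, n_frames: int) -> np.ndarray:
    """Per-frame detection counts over the whole video length."""
    if n_frames <= 0:
        raise ParameterError("n_frames must be positive")
    counts = np.zeros(n_frames, dtype=int)
    for det in dets:
        if det.frame_idx >= n_frames:
            raise ParameterError(
                f"frame index {det.frame_idx} outside video of {n_frames} frames"
            )
        counts[det.frame_idx] += 1
    return counts


# ---------------------------------------------------------------------------
# I/O: CSV dialect and YOLO-style per-frame text files
# ---------------------------------------------------------------------------

_CSV_HEADER = ["frame_idx", "x1", "y1", "x2", "y2", "confidence", "label"]


def write_detections_csv(dets: DetectionSet, path: str | Path) -> None:
    """Write detections as CSV; floats use ``repr`` so reads round-trip bit-exactly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for d in dets:
            writer.writerow(
                [d.frame_idx, repr(float(d.box.x1)), repr(float(d.box.y1)),
                 repr(float(d.box.x2)), repr(float(d.box.y2)),
                 repr(float(d.confidence)), d.label]
            )


def read_detections_csv(path: str | Path) -> DetectionSet:
    dets: List[Detection] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ParameterError(f"detection CSV missing columns: {sorted(missing)}")
        for row in reader:
            dets.append(
                Detection(
                    frame_idx=int(row["frame_idx"]),
                    box=Rect(float(row["x1"]), float(row["y1"]),
                             float(row["x2"]), float(row["y2"])),
                    confidence=float(row["confidence"]),
                    label=row["label"],
                )
            )
    return DetectionSet(detections=dets, metadata={"source_path": str(path)})


def read_yolo_frame(
    path: str | Path,
    frame_idx: int,
    width_px: int,
    height_px: int,
    label: str = "bumblebee",
) -> List[Detection]:
    """Parse one YOLO-style text file: ``class cx cy w h conf`` (normalised)."""
    dets: List[Detection] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 6:
            raise ParameterError(f"malformed YOLO line in {path}: {line!r}")
        _, cx, cy, w, h, conf = (float(p) for p in parts[:6])
        bw, bh = w * width_px, h * height_px
        x, y = cx * width_px, cy * height_px
        dets.append(
            Detection(
                frame_idx=frame_idx,
                box=Rect(x - bw / 2, y - bh / 2, x + bw / 2, y + bh / 2),
                confidence=conf,
                label=label,
            )
        )
    return dets


_FRAME_IDX_RE = re.compile(r"(\d+)(?=\D*$)")


def frame_index_from_name(name: str) -> int:
    """Frame index = last run of digits in the file stem."""
    match = _FRAME_IDX_RE.search(Path(name).stem)
    if match is None:
        raise ParameterError(f"no frame index found in filename {name!r}")
    return int(match.group(1))


def read_yolo_dir(
    directory: str | Path,
    width_px: int,
    height_px: int,
    pattern: str = "*.txt",
) -> DetectionSet:
    """Read a directory of YOLO per-frame files, index parsed from filenames."""
    dets: List[Detection] = []
    for path in sorted(Path(directory).glob(pattern)):
        dets.extend(
            read_yolo_frame(path, frame_index_from_name(path.name), width_px, height_px)
        )
    return DetectionSet(detections=dets, metadata={"source_path": str(directory)})
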