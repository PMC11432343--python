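"""Seed-controlled synthetic scenes and detection streams with known truth.

Scenes are flower patches rendered directly in internal-scale HSV: coloured
disks (strictly inside a target colour band) on a band-separable background,
with bumblebee-sized dark ellipses stamped on top.  Streams are per-frame
detection records with known attractiveness, on-flower probability, and
optional near-coincident duplicate boxes that exercise the merge step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from beeforage.colour import ColourBand, band_mask
from beeforage.detections import Detection, DetectionSet
from beeforage.errors import ParameterError
from beeforage.geometry import FrameGeometry, QuadratSpec, Rect, quadrat_rect

__all__ = [
    "FlowerDisk",
    "BeeEllipse",
    "SceneSpec",
    "StreamSpec",
    "SyntheticTruth",
    "render_scene",
    "random_scene",
    "emit_stream",
    "make_labelled_video",
    "BEE_COLOUR",
]

Triplet = Tuple[int, int, int]

#: Dark, unsaturated bee colour; fails every shipped flower band.
BEE_COLOUR: Triplet = (20, 30, 25)


@dataclass(frozen=True)
class FlowerDisk:
    """One circular flower region."""

    cx: float
    cy: float
    radius: float
    colour: Triplet

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("disk radius must be positive")


@dataclass(frozen=True)
class BeeEllipse:
    """A bumblebee-like dark ellipse (half-axes in pixels)."""

    cx: float
    cy: float
    half_len: float
    half_width: float
    angle_deg: float = 0.0
    colour: Triplet = BEE_COLOUR

    def box(self) -> Rect:
        """Axis-aligned bounding box of the rotated ellipse."""
        theta = math.radians(self.angle_deg)
        hx = math.hypot(self.half_len * math.cos(theta), self.half_width * math.sin(theta))
        hy = math.hypot(self.half_len * math.sin(theta), self.half_width * math.cos(theta))
        return Rect(self.cx - hx, self.cy - hy, self.cx + hx, self.cy + hy)


@dataclass
class SceneSpec:
    """A static flower patch plus per-frame bee placements."""

    width_px: int
    height_px: int
    mm_per_px: float
    quadrat: QuadratSpec
    flowers: List[FlowerDisk]
    background: Triplet = (60, 20, 60)
    bee_frames: List[List[BeeEllipse]] = field(default_factory=lambda: [[]])
    fps: float = 30.0

    def geometry(self) -> FrameGeometry:
        return FrameGeometry(self.width_px, self.height_px, self.mm_per_px, self.fps)


@dataclass
class StreamSpec:
    """Statistical structure of a synthetic detection stream."""

    n_frames: int
    mean_count: float  # expected bees per frame (lambda)
    p_on: float = 0.5
    duplicate_rate: float = 0.0
    duplicate_offset_px: float = 5.0
    conf_range: Tuple[float, float] = (0.75, 1.0)
    box_size_px: float = 48.0
    mean_stay_frames: float = 1.0  # >1 gives geometric presence runs

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ParameterError("n_frames must be positive")
        if self.mean_count < 0:
            raise ParameterError("mean_count must be non-negative")
        if not 0.0 <= self.p_on <= 1.0:
            raise ParameterError("p_on must lie in [0, 1]")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ParameterError("duplicate_rate must lie in [0, 1]")
        if self.mean_stay_frames < 1.0:
            raise ParameterError("mean_stay_frames must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a scene or stream."""

    true_cover: Optional[float] = None
    counts: Optional[np.ndarray] = None
    boxes_by_frame: Dict[int, List[Rect]] = field(default_factory=dict)
    on_flower: List[bool] = field(default_factory=list)
    merged_inventory: List[Detection] = field(default_factory=list)
    meta: Dict[str, object] = field(default_factory=dict)


def _disk_mask(shape: Tuple[int, int], disk: FlowerDisk) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    # pixel centre at (x + 0.5, y + 0.5)
    return (xx + 0.5 - disk.cx) ** 2 + (yy + 0.5 - disk.cy) ** 2 <= disk.radius**2


def _ellipse_mask(shape: Tuple[int, int], bee: BeeEllipse) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    dx = xx + 0.5 - bee.cx
    dy = yy + 0.5 - bee.cy
    theta = math.radians(bee.angle_deg)
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (u / bee.half_len) ** 2 + (v / bee.half_width) ** 2 <= 1.0


def render_scene(spec: SceneSpec, band: Optional[ColourBand] = None) -> Tuple[List[np.ndarray], SyntheticTruth]:
    """Rasterise the scene: one frame per entry of ``bee_frames``.

    The recorded true cover is the painted flower fraction of the quadrat
    in the bee-free base image (exact pixel count, so downstream cover
    estimates can be checked to rasterisation error).  When ``band`` is
    given, the cover of in-band pixels is recorded instead of painted
    pixels (identical when all disk colours sit inside the band).
    """
    geom = spec.geometry()
    shape = (spec.height_px, spec.width_px)
    base = np.empty((*shape, 3), dtype=np.uint8)
    base[..., 0], base[..., 1], base[..., 2] = spec.background
    flower_mask = np.zeros(shape, dtype=bool)
    for disk in spec.flowers:
        mask = _disk_mask(shape, disk)
        flower_mask |= mask
        base[mask] = disk.colour

    rect = quadrat_rect(spec.quadrat, geom)
    ys = slice(int(rect.y1), int(rect.y2))
    xs = slice(int(rect.x1), int(rect.x2))
    if band is None:
        in_quadrat = flower_mask[ys, xs]
    else:
        in_quadrat = band_mask(base[ys, xs], band)
    true_cover = float(in_quadrat.sum()) / in_quadrat.size

    frames: List[np.ndarray] = []
    boxes_by_frame: Dict[int, List[Rect]] = {}
    for t, bees in enumerate(spec.bee_frames):
        frame = base.copy()
        boxes: List[Rect] = []
        for bee in bees:
            box = bee.box()
            if box.x1 < 0 or box.y1 < 0 or box.x2 > spec.width_px or box.y2 > spec.height_px:
                raise ParameterError(f"bee {bee} extends outside the frame")
            frame[_ellipse_mask(shape, bee)] = bee.colour
            boxes.append(box)
        frames.append(frame)
        if boxes:
            boxes_by_frame[t] = boxes

    counts = np.array([len(bees) for bees in spec.bee_frames], dtype=int)
    truth = SyntheticTruth(
        true_cover=true_cover,
        counts=counts,
        boxes_by_frame=boxes_by_frame,
        meta={"quadrat_rect": rect.as_tuple()},
    )
    return frames, truth


def _in_band_colour(band: ColourBand, rng: np.random.Generator, margin: int = 3) -> Triplet:
    """A random colour comfortably inside the band on every channel.

    ``margin`` keeps the colour away from band edges so uint8 RGB
    round-trips cannot flip membership.  Inverted channels draw from the
    wider lobe of the complement pass band.
    """
    colour = []
    for c in range(3):
        lo, hi = band.lower[c], band.upper[c]
        if c in (band.inverted_channels or ()):
            # lobes: [lo, 255] and [0, hi]
            upper_lobe = (min(lo + margin, 255), 255)
            lower_lobe = (0, max(hi - margin, 0))
            lobe = upper_lobe if (255 - lo) >= hi else lower_lobe
            colour.append(int(rng.integers(lobe[0], lobe[1] + 1)))
        else:
            a, b = lo + margin, hi - margin
            if a > b:  # very narrow band: use the midpoint
                a = b = (lo + hi) // 2
            colour.append(int(rng.integers(a, b + 1)))
    return tuple(colour)  # type: ignore[return-value]


def random_scene(
    band: ColourBand,
    rng: np.random.Generator,
    width_px: int = 320,
    height_px: int = 320,
    mm_per_px: float = 2.0,
    n_disks: Tuple[int, int] = (1, 6),
    radius_px: Tuple[float, float] = (10.0, 45.0),
    background: Triplet = (60, 20, 60),
) -> SceneSpec:
    """A random quadrat-filling scene with disks coloured inside ``band``."""
    side_px = min(width_px, height_px)
    quadrat = QuadratSpec(corner_x_px=0, corner_y_px=0, side_mm=side_px * mm_per_px)
    k = int(rng.integers(n_disks[0], n_disks[1] + 1))
    disks = [
        FlowerDisk(
            cx=float(rng.uniform(0, side_px)),
            cy=float(rng.uniform(0, side_px)),
            radius=float(rng.uniform(*radius_px)),
            colour=_in_band_colour(band, rng),
        )
        for _ in range(k)
    ]
    return SceneSpec(
        width_px=width_px,
        height_px=height_px,
        mm_per_px=mm_per_px,
        quadrat=quadrat,
        flowers=disks,
        background=background,
    )


def _draw_counts(spec: StreamSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-frame counts: i.i.d. Poisson, or an arrival/stay run process.

    With geometric stays of mean ``m`` and Poisson arrivals at rate
    ``lambda / m``, the stationary per-frame mean remains ``lambda``.
    """
    if spec.mean_stay_frames == 1.0:
        return rng.poisson(spec.mean_count, size=spec.n_frames)
    m = spec.mean_stay_frames
    counts = np.zeros(spec.n_frames, dtype=int)
    arrivals = rng.poisson(spec.mean_count / m, size=spec.n_frames)
    for t in range(spec.n_frames):
        for _ in range(int(arrivals[t])):
            stay = int(rng.geometric(1.0 / m))
            counts[t : t + stay] += 1
    return counts


def emit_stream(
    spec: StreamSpec,
    geometry: FrameGeometry,
    seed: Optional[int] = None,
    rect: Optional[Rect] = None,
) -> Tuple[DetectionSet, SyntheticTruth]:
    """Synthetic raw detections with known per-frame truth.

    True boxes are placed uniformly inside ``rect`` (default: the whole
    frame); each true box spawns, with probability ``duplicate_rate``, a
    near-coincident duplicate whose centroid offset is strictly below
    ``duplicate_offset_px`` — mimicking double detections at tile seams.
    Confidences are uniform over ``conf_range``; on-flower truth labels
    are Bernoulli(``p_on``) per true box.
    """
    rng = np.random.default_rng(seed)
    if rect is None:
        rect = Rect(0, 0, geometry.width_px, geometry.height_px)
    half = spec.box_size_px / 2.0
    if rect.width <= spec.box_size_px or rect.height <= spec.box_size_px:
        raise ParameterError("placement region is smaller than the box size")

    counts = _draw_counts(spec, rng)
    raw: List[Detection] = []
    truth_boxes: Dict[int, List[Rect]] = {}
    on_flower: List[bool] = []
    inventory: List[Detection] = []
    for t in range(spec.n_frames):
        for _ in range(int(counts[t])):
            cx = float(rng.uniform(rect.x1 + half, rect.x2 - half))
            cy = float(rng.uniform(rect.y1 + half, rect.y2 - half))
            box = Rect(cx - half, cy - half, cx + half, cy + half)
            conf = float(rng.uniform(*spec.conf_range))
            det = Detection(frame_idx=t, box=box, confidence=conf)
            raw.append(det)
            inventory.append(det)
            truth_boxes.setdefault(t, []).append(box)
            on_flower.append(bool(rng.random() < spec.p_on))
            if rng.random() < spec.duplicate_rate:
                angle = rng.uniform(0, 2 * math.pi)
                r = rng.uniform(0, spec.duplicate_offset_px * 0.999)
                dup_box = box.translate(r * math.cos(angle), r * math.sin(angle))
                raw.append(
                    Detection(
                        frame_idx=t,
                        box=dup_box,
                        confidence=float(rng.uniform(*spec.conf_range)),
                    )
                )
    dets = DetectionSet(
        detections=raw,
        metadata={"seed": seed, "stream": spec.__dict__.copy()},
    )
    truth = SyntheticTruth(
        counts=counts,
        boxes_by_frame=truth_boxes,
        on_flower=on_flower,
        merged_inventory=inventory,
        meta={"lambda": spec.mean_count, "p_on": spec.p_on},
    )
    return dets, truth


def make_labelled_video(
    band: ColourBand,
    n_frames: int = 8,
    bees_per_frame: int = 2,
    p_on: float = 0.5,
    seed: Optional[int] = None,
    frame_px: int = 320,
    mm_per_px: float = 2.0,
) -> Tuple[List[np.ndarray], DetectionSet, SyntheticTruth]:
    """An end-to-end scene: frames, exact detections and on/off-flower truth.

    Frame 0 is bee-free (a guaranteed reference frame).  On-flower bees sit
    at the centre of a large flower disk (box fully flower-covered);
    off-flower bees sit in pure background, far from every disk, so the
    colour-band classifier must reproduce the truth labels exactly.
    """
    rng = np.random.default_rng(seed)
    side = frame_px
    quadrat = QuadratSpec(0, 0, side_mm=side * mm_per_px)
    bee_half_len = 30.0 / mm_per_px / 2.0  # 30 mm body
    disk_r = bee_half_len * 3.0

    # two flower disks in the left half, background kept clear on the right
    disks = [
        FlowerDisk(side * 0.25, side * 0.25, disk_r, _in_band_colour(band, rng)),
        FlowerDisk(side * 0.25, side * 0.70, disk_r, _in_band_colour(band, rng)),
    ]
    bee_frames: List[List[BeeEllipse]] = [[]]
    labels: List[bool] = []
    dets: List[Detection] = []
    for t in range(1, n_frames):
        bees: List[BeeEllipse] = []
        for b in range(bees_per_frame):
            on = bool(rng.random() < p_on)
            if on:
                disk = disks[int(rng.integers(len(disks)))]
                cx, cy = disk.cx, disk.cy
            else:
                cx = float(rng.uniform(side * 0.65, side * 0.9))
                cy = float(rng.uniform(side * 0.1, side * 0.9))
            bee = BeeEllipse(cx, cy, bee_half_len, bee_half_len / 2,
                             angle_deg=float(rng.uniform(0, 180)))
            bees.append(bee)
            labels.append(on)
            dets.append(Detection(frame_idx=t, box=bee.box(), confidence=0.95))
        bee_frames.append(bees)

    scene = SceneSpec(
        width_px=frame_px,
        height_px=frame_px,
        mm_per_px=mm_per_px,
        quadrat=quadrat,
        flowers=disks,
        bee_frames=bee_frames,
    )
    frames, truth = render_scene(scene, band=band)
    truth.on_flower = labels
    truth.meta["p_on"] = p_on
    det_set = DetectionSet(detections=dets, metadata={"seed": seed, "synthetic": True})
    return frames, det_set, truth
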