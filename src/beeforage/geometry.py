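"""Pixel/physical coordinate conversion, quadrat placement and frame tiling.

Conventions
-----------
Pixel coordinates are 0-based.  Rectangles are half-open: a :class:`Rect`
``(x1, y1, x2, y2)`` contains pixel centres ``x1 <= x < x2`` and
``y1 <= y < y2``, so areas and membership tests are exact integer
arithmetic.  The millimetre-per-pixel scale is assumed isotropic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Tuple

import yaml

from beeforage.errors import CalibrationError, OutOfFrameError, ParameterError

__all__ = [
    "Rect",
    "FrameGeometry",
    "QuadratSpec",
    "TileGrid",
    "Calibration",
    "calibrate_scale",
    "frames_in_segment",
    "make_tile_grid",
    "tile_box_to_frame",
    "frame_box_to_tile",
    "quadrat_rect",
    "centroid_in_quadrat",
    "load_calibration",
    "save_calibration",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open rectangle ``[x1, x2) x [y1, y2)``."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ParameterError(f"degenerate rectangle: {self!r}")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def centroid(self) -> Tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def contains_point(self, x: float, y: float) -> bool:
        """Half-open membership: near edges included, far edges excluded."""
        return self.x1 <= x < self.x2 and self.y1 <= y < self.y2

    def intersects(self, other: "Rect") -> bool:
        return (
            self.x1 < other.x2
            and other.x1 < self.x2
            and self.y1 < other.y2
            and other.y1 < self.y2
        )

    def translate(self, dx: float, dy: float) -> "Rect":
        return Rect(self.x1 + dx, self.y1 + dy, self.x2 + dx, self.y2 + dy)

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


@dataclass(frozen=True)
class FrameGeometry:
    """Calibrated geometry of one recording setup."""

    width_px: int
    height_px: int
    mm_per_px: float
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ParameterError("frame dimensions must be positive")
        if self.mm_per_px <= 0:
            raise ParameterError("mm_per_px must be positive")
        if self.fps <= 0:
            raise ParameterError("fps must be positive")

    def mm_to_px(self, mm: float) -> float:
        return mm / self.mm_per_px

    def px_to_mm(self, px: float) -> float:
        return px * self.mm_per_px


@dataclass(frozen=True)
class QuadratSpec:
    """Placement of the physical analysis square, anchored at its upper-left corner."""

    corner_x_px: float
    corner_y_px: float
    side_mm: float = 600.0

    def __post_init__(self) -> None:
        if self.side_mm <= 0:
            raise ParameterError("side_mm must be positive")


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping tiling of a (padded) frame into square tiles."""

    tile_px: int
    padded_width_px: int
    padded_height_px: int
    n_cols: int
    n_rows: int

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows

    def tiles(self) -> Iterator[Tuple[int, int]]:
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield (row, col)

    def tile_rect(self, row: int, col: int) -> Rect:
        self._check_index(row, col)
        return Rect(
            col * self.tile_px,
            row * self.tile_px,
            (col + 1) * self.tile_px,
            (row + 1) * self.tile_px,
        )

    def _check_index(self, row: int, col: int) -> None:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ParameterError(
                f"tile index ({row}, {col}) outside {self.n_rows} x {self.n_cols} grid"
            )


def calibrate_scale(scalebar_length_px: float, scalebar_length_mm: float) -> float:
    """Millimetres per pixel from a scale bar of known physical length.

    Raises
    ------
    CalibrationError
        If either length is not strictly positive.
    """
    if scalebar_length_px <= 0 or scalebar_length_mm <= 0:
        raise CalibrationError(
            "scale-bar lengths must be positive, got "
            f"{scalebar_length_px} px / {scalebar_length_mm} mm"
        )
    return scalebar_length_mm / scalebar_length_px


def frames_in_segment(duration_s: float, fps: float) -> int:
    """Number of frames in a video segment of ``duration_s`` seconds."""
    if duration_s <= 0 or fps <= 0:
        raise ParameterError("duration and fps must be positive")
    return round(duration_s * fps)


def make_tile_grid(geometry: FrameGeometry, tile_px: int = 640) -> TileGrid:
    """Smallest tiling of the frame with ``tile_px`` square tiles.

    The frame is padded (right/bottom) to the smallest multiples of
    ``tile_px`` that contain it; the tiles then cover the padded frame
    exactly once.
    """
    if tile_px <= 0:
        raise ParameterError("tile_px must be positive")
    n_cols = -(-geometry.width_px // tile_px)
    n_rows = -(-geometry.height_px // tile_px)
    return TileGrid(
        tile_px=tile_px,
        padded_width_px=n_cols * tile_px,
        padded_height_px=n_rows * tile_px,
        n_cols=n_cols,
        n_rows=n_rows,
    )


def tile_box_to_frame(box_in_tile: Rect, tile_index: Tuple[int, int], grid: TileGrid) -> Rect:
    """Map a box from tile-local coordinates back to frame coordinates."""
    row, col = tile_index
    grid._check_index(row, col)
    return box_in_tile.translate(col * grid.tile_px, row * grid.tile_px)


def frame_box_to_tile(box: Rect, grid: TileGrid) -> Tuple[Rect, Tuple[int, int]]:
    """Map a frame-coordinate box into the single tile that contains it.

    Raises
    ------
    ParameterError
        If the box straddles a tile boundary or lies outside the grid.
    """
    col = int(box.x1 // grid.tile_px)
    row = int(box.y1 // grid.tile_px)
    grid._check_index(row, col)
    tile = grid.tile_rect(row, col)
    if not (box.x2 <= tile.x2 and box.y2 <= tile.y2):
        raise ParameterError(f"box {box} is not contained in a single tile")
    return box.translate(-tile.x1, -tile.y1), (row, col)


def quadrat_rect(q: QuadratSpec, g: FrameGeometry) -> Rect:
    """Pixel rectangle of the quadrat, anchored at its recorded corner.

    Side length is ``round(side_mm / mm_per_px)`` pixels.  Raises
    :class:`OutOfFrameError` listing the overflow when the rectangle
    exceeds the frame bounds.
    """
    side_px = round(g.mm_to_px(q.side_mm))
    rect = Rect(q.corner_x_px, q.corner_y_px, q.corner_x_px + side_px, q.corner_y_px + side_px)
    overflow = []
    if rect.x1 < 0:
        overflow.append(f"left by {-rect.x1:g} px")
    if rect.y1 < 0:
        overflow.append(f"top by {-rect.y1:g} px")
    if rect.x2 > g.width_px:
        overflow.append(f"right by {rect.x2 - g.width_px:g} px")
    if rect.y2 > g.height_px:
        overflow.append(f"bottom by {rect.y2 - g.height_px:g} px")
    if overflow:
        raise OutOfFrameError(
            f"quadrat exceeds the {g.width_px} x {g.height_px} frame: " + ", ".join(overflow)
        )
    return rect


def centroid_in_quadrat(box: Rect, rect: Rect) -> bool:
    """Whether the box centroid lies within the half-open quadrat rectangle."""
    cx, cy = box.centroid
    return rect.contains_point(cx, cy)


@dataclass(frozen=True)
class Calibration:
    """One setup's calibration record, as stored next to each video."""

    scalebar_px: float
    scalebar_mm: float
    quadrat_corner_xy: Tuple[float, float]
    side_mm: float = 600.0
    fps: float = 30.0
    frame_width_px: int = 5120
    frame_height_px: int = 2880
    extra: dict = field(default_factory=dict)

    @property
    def mm_per_px(self) -> float:
        return calibrate_scale(self.scalebar_px, self.scalebar_mm)

    def geometry(self) -> FrameGeometry:
        return FrameGeometry(
            width_px=self.frame_width_px,
            height_px=self.frame_height_px,
            mm_per_px=self.mm_per_px,
            fps=self.fps,
        )

    def quadrat(self) -> QuadratSpec:
        return QuadratSpec(
            corner_x_px=self.quadrat_corner_xy[0],
            corner_y_px=self.quadrat_corner_xy[1],
            side_mm=self.side_mm,
        )


def load_calibration(path: str | Path) -> Calibration:
    """Read a calibration record from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    known = {"scalebar_px", "scalebar_mm", "quadrat_corner_xy", "side_mm", "fps",
             "frame_width_px", "frame_height_px"}
    kwargs = {k: v for k, v in data.items() if k in known}
    kwargs["quadrat_corner_xy"] = tuple(kwargs["quadrat_corner_xy"])
    extra = {k: v for k, v in data.items() if k not in known}
    return Calibration(extra=extra, **kwargs)


def save_calibration(cal: Calibration, path: str | Path) -> None:
    path = Path(path)
    data = {
        "scalebar_px": cal.scalebar_px,
        "scalebar_mm": cal.scalebar_mm,
        "quadrat_corner_xy": list(cal.quadrat_corner_xy),
        "side_mm": cal.side_mm,
        "fps": cal.fps,
        "frame_width_px": cal.frame_width_px,
        "frame_height_px": cal.frame_height_px,
        **cal.extra,
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
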