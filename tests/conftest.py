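import numpy as np
import pytest

from beeforage import DEFAULT_BANDS, FrameGeometry, QuadratSpec
from beeforage.detections import Detection
from beeforage.geometry import Rect


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return FrameGeometry(width_px=640, height_px=640, mm_per_px=1.0, fps=30.0)


@pytest.fixture
def field_geometry():
    """The recording geometry used in the field."""
    return FrameGeometry(width_px=5120, height_px=2880, mm_per_px=1.0, fps=30.0)


@pytest.fixture
def quadrat():
    return QuadratSpec(corner_x_px=0, corner_y_px=0, side_mm=600.0)


@pytest.fixture(params=sorted(DEFAULT_BANDS))
def band(request):
    return DEFAULT_BANDS[request.param]


@pytest.fixture
def lotus_band():
    return DEFAULT_BANDS["lotus"]


def make_det(frame_idx, cx, cy, size=20.0, confidence=0.9, **kw):
    half = size / 2
    return Detection(
        frame_idx=frame_idx,
        box=Rect(cx - half, cy - half, cx + half, cy + half),
        confidence=confidence,
        **kw,
    )


@pytest.fixture
def det_factory():
    return make_det


def random_boxes(rng, n, extent=600.0, size_range=(5.0, 40.0)):
    """Random valid boxes inside [0, extent)^2."""
    boxes = []
    for _ in range(n):
        w, h = rng.uniform(*size_range, size=2)
        x1 = rng.uniform(0, extent - w)
        y1 = rng.uniform(0, extent - h)
        boxes.append(Rect(x1, y1, x1 + w, y1 + h))
    return boxes


@pytest.fixture
def box_factory():
    return random_boxes
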