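import numpy as np
import pytest

from diatile import (
    GroundTruth,
    Instance,
    Rect,
    SlideImage,
    SyntheticConfig,
    generate_slide,
)


@pytest.fixture(scope="session")
def small_slide():
    """A 1024x1024 synthetic slide with a handful of objects + clutter."""
    cfg = SyntheticConfig(
        width=1024, height=1024, n_objects=4, n_fragments=2, n_debris=3,
        n_bands=1, object_length_range=(60.0, 160.0), seed=11,
    )
    return generate_slide(cfg)


@pytest.fixture(scope="session")
def default_slide():
    """The default 2048x2048 synthetic slide (12 objects)."""
    return generate_slide(SyntheticConfig(seed=7))


def make_rect_instance(instance_id, r0, c0, h, w):
    """A solid rectangular instance — handy for exact-area geometry tests."""
    return Instance(instance_id, Rect(r0, c0, r0 + h, c0 + w),
                    np.ones((h, w), dtype=bool))


def make_slide(h, w, level=220):
    return SlideImage(np.full((h, w), level, dtype=np.uint8))


@pytest.fixture
def rect_world():
    """A 1200x1600 blank slide plus a ground truth of solid rectangles."""
    slide = make_slide(1200, 1600)
    gt = GroundTruth((1200, 1600), [
        make_rect_instance(1, 300, 400, 100, 60),
        make_rect_instance(2, 700, 900, 40, 200),
    ])
    return slide, gt
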