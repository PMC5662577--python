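import numpy as np
import pytest

import dopplervi as dv


@pytest.fixture(scope="session")
def disc_mask() -> dv.ROIMask:
    """Filled disc of diameter 101 px (radius 50) on a 121x121 grid."""
    yy, xx = np.mgrid[0:121, 0:121]
    return dv.ROIMask((yy - 60) ** 2 + (xx - 60) ** 2 <= 50**2)


@pytest.fixture(scope="session")
def phantom() -> dv.PhantomResult:
    """One default phantom (blob radius 60, targets 30%/10% at 22% offset)."""
    return dv.generate_phantom(dv.PhantomSpec(seed=1))


def make_rect_outline_image(
    height=20, width=20, top=5, left=5, size=10, color=(0, 255, 0), grey=120
):
    """Axis-aligned rectangular outline of side `size` (outer), 1 px thick."""
    px = np.full((height, width, 3), grey, dtype=np.uint8)
    b, r = top + size - 1, left + size - 1
    px[top, left : r + 1] = color
    px[b, left : r + 1] = color
    px[top : b + 1, left] = color
    px[top : b + 1, r] = color
    return dv.AnnotatedImage(px, annotation_color=color)
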