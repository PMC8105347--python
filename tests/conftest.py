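import numpy as np
import pytest
from hypothesis import settings

from seedmorph.imaging import Outline

settings.register_profile("ci", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("ci")


def circle_outline(r=1.0, n=360, center=(0.0, 0.0)):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Outline(points=np.column_stack([center[0] + r * np.cos(th),
                                           center[1] + r * np.sin(th)]))


def ellipse_outline(a=2.0, b=1.0, n=720):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Outline(points=np.column_stack([a * np.cos(th), b * np.sin(th)]))


def random_smooth_outline(rng, n=360):
    """A random smooth star-convex closed curve."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = np.ones(n)
    for m in range(1, 6):
        amp = 0.15 / m
        r += amp * (rng.uniform(-1, 1) * np.cos(m * th)
                    + rng.uniform(-1, 1) * np.sin(m * th))
    return Outline(points=np.column_stack([r * np.cos(th), r * np.sin(th)]))


def band_limited_shape(rng, H=5, k=1440, iters=10):
    """Coefficients of a shape exactly representable with H harmonics.

    Iterating transform -> reconstruct converges to a fixed point whose
    arc-length parameterization is consistent with its own truncated
    series; only such shapes can round-trip exactly.
    """
    from seedmorph import efa
    c = efa.efourier(random_smooth_outline(rng), H)
    for _ in range(iters):
        c = efa.efourier(
            efa.resample_outline(efa.inverse_efourier(c, k), k), H)
    return c


def landmarks_for(outline):
    """Deterministic 5-point landmark configuration on an outline."""
    from seedmorph.synthetic import auto_landmarks
    return auto_landmarks(outline)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
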