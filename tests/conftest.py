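"""Shared fixtures: small synthetic stacks and traces built at test time."""

import numpy as np
import pytest

from neurotrace.image_stack import ImageStack
from neurotrace.synthetic import SyntheticSpec, TubeSpec, render_stack
from neurotrace.trace_model import Trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_tube():
    """A clean straight tube along x with its ground-truth trace."""
    spec = SyntheticSpec(
        shape=(60, 14, 10),
        tubes=[TubeSpec(points=[[3, 7, 5], [56, 7, 5]], sigma=1.2, amplitude=0.9)],
        background=0.05,
        noise_std=0.0,
        rng_seed=7,
    )
    return render_stack(spec)


@pytest.fixture
def y_tube():
    """Three arms meeting at one point: a single true branch point."""
    arms = [
        TubeSpec(points=[[20, 20, 5], [4, 4, 5]], sigma=1.2, amplitude=0.9),
        TubeSpec(points=[[20, 20, 5], [36, 4, 5]], sigma=1.2, amplitude=0.9),
        TubeSpec(points=[[20, 20, 5], [20, 38, 5]], sigma=1.2, amplitude=0.9),
    ]
    spec = SyntheticSpec(shape=(40, 40, 10), tubes=arms, background=0.05,
                         noise_std=0.01, rng_seed=4)
    return render_stack(spec)


def make_path_trace(points, caliber=1.0):
    """A path trace through the given positions."""
    t = Trace()
    prev = None
    for p in points:
        n = t.add_node(p, caliber)
        if prev is not None:
            t.add_edge(prev, n)
        prev = n
    return t


def make_y_trace(center=(0.0, 0.0, 0.0), arm=10, step=1.0):
    """A Y-shaped trace: three straight arms from a center node."""
    t = Trace()
    c = t.add_node(center)
    for d in [(1, 0, 0), (-1, 1, 0), (-1, -1, 0)]:
        d = np.array(d, dtype=float)
        d /= np.linalg.norm(d)
        prev = c
        for i in range(1, arm + 1):
            n = t.add_node(np.array(center) + d * i * step)
            t.add_edge(prev, n)
            prev = n
    return t


def uniform_stack(shape=(12, 12, 6), value=1.0, voxel_size=(1.0, 1.0, 1.0)):
    return ImageStack(np.full(shape, value), voxel_size)


# the label-correcting arrival-time oracle lives in neurotrace.benchmarks;
# re-exported here for the solver tests
from neurotrace.benchmarks import eikonal_fixed_point  # noqa: E402,F401
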