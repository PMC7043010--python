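"""Shared fixtures: RNG, a small fast phantom case, and its segmentation."""

import numpy as np
import pytest
from hypothesis import settings

from stackellipse.phantom import PhantomSpec, make_case
from stackellipse.segmentation import segment_volume
from stackellipse.training import default_axis_model

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(**overrides) -> PhantomSpec:
    """A reduced phantom (shorter organ, 1 mm voxels) for fast unit tests."""
    kwargs = dict(
        control_points=((-18.0, 14.0), (-4.0, 10.0), (2.0, -16.0)),
        b_start=12.0,
        b_end=7.0,
        spacing=1.0,
        margin=6.0,
        truth_slice_spacing=2.0,
        speckle_strength=0.0,
        seed=7,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_case():
    return make_case(small_spec())


@pytest.fixture(scope="session")
def small_result(small_case):
    return segment_volume(
        small_case.volume, small_case.init, default_axis_model()
    )
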