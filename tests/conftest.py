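"""Shared fixtures: miniature study objects that keep unit tests fast.

The tiny configuration is one fundamental map block (4 x 4 mm) with an
8 s protocol; full-size (12 mm / 23 s) objects are only built by the
acceptance tests.
"""

import numpy as np
import pytest

from odcolumn import (
    GridSpec,
    HemodynamicParams,
    Stimulus,
    build_activity,
    build_map,
    predict_bold,
    transfer_function,
)


@pytest.fixture(scope="session")
def tiny_map():
    return build_map(h=0.125, blocks=1)


@pytest.fixture(scope="session")
def tiny_grid(tiny_map):
    return GridSpec.from_extent(
        tiny_map.extent_x, tiny_map.extent_y, h=0.125, duration=8.0, dt=0.1
    )


@pytest.fixture(scope="session")
def tiny_stim():
    return Stimulus(op_angle=0.0, onset=1.0, offset=4.0)


@pytest.fixture(scope="session")
def tiny_activity(tiny_map, tiny_grid, tiny_stim):
    return build_activity(tiny_map, tiny_stim, tiny_grid)


@pytest.fixture(scope="session")
def tiny_transfer(tiny_grid):
    return transfer_function(HemodynamicParams(), tiny_grid)


@pytest.fixture(scope="session")
def tiny_bold(tiny_activity, tiny_transfer):
    return predict_bold(tiny_activity, tiny_transfer)


@pytest.fixture(scope="session")
def proto_grid():
    """Small patch but the full 23 s protocol (for temporal-shape tests)."""
    return GridSpec.from_extent(4.0, 4.0, h=0.125, duration=23.0, dt=0.1)


@pytest.fixture(scope="session")
def proto_transfer(proto_grid):
    return transfer_function(HemodynamicParams(), proto_grid)


@pytest.fixture(scope="session")
def proto_bold(proto_grid, proto_transfer):
    fmap = build_map(h=0.125, blocks=1)
    phi = build_activity(fmap, Stimulus(), proto_grid)
    return phi, predict_bold(phi, proto_transfer)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
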