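"""Shared fixtures: small phantoms for unit tests, the default-size phantom
for end-to-end validation.  Everything is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from lvflow import PhantomSpec, TraceConfig, generate_lv_phantom, trace_all

#: a fast 32-cube phantom used by most unit tests (slower blood so the pool's
#: travel fits the smaller grid)
SMALL_KW = dict(grid_shape=(32, 32, 32), peak_speed_m_s=0.05)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(**SMALL_KW)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_lv_phantom(small_spec)


@pytest.fixture(scope="session")
def small_pathlines(small_phantom):
    return trace_all(small_phantom.field, small_phantom.edv_mask, TraceConfig())


@pytest.fixture(scope="session")
def default_phantom():
    """The default 64-cube, 20-frame phantom with rest-like fractions."""
    return generate_lv_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_pathlines(default_phantom):
    return trace_all(default_phantom.field, default_phantom.edv_mask, TraceConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
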