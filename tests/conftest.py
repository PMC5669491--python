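"""Shared fixtures: domains, connectivity, and orientation maps.

Heavy objects (the reduced-schedule learned map) are session-scoped so the
expensive Hebbian learning runs once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import v1field as vf
from v1field.orientation_map import MapLearningConfig, band_filter, learn_map, synthetic_map


@pytest.fixture(scope="session")
def dom64() -> vf.Domain:
    return vf.Domain(L=30.0, N=64)


@pytest.fixture(scope="session")
def dom128() -> vf.Domain:
    return vf.Domain(L=30.0, N=128)


@pytest.fixture(scope="session")
def default_profile() -> vf.ConnectivityProfile:
    return vf.build_profile(vf.ConnectivityParams())


@pytest.fixture(scope="session")
def kernels64(default_profile, dom64):
    return vf.grid_kernels(default_profile, dom64)


@pytest.fixture(scope="session")
def synth_map128(dom128):
    return synthetic_map(dom128, seed=7)


@pytest.fixture(scope="session")
def synth_map64(dom64):
    return synthetic_map(dom64, seed=7)


@pytest.fixture(scope="session")
def learned_map64(dom64, kernels64):
    """Reduced-schedule Hebbian map: 800 presentations on the 64² grid."""
    cfg = MapLearningConfig(steps=800, check_every=400, seed=3, t_learn=150.0, dt=2.0)
    return learn_map(cfg, dom64, kernels64)
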