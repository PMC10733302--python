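"""Shared fixtures.

Expensive built objects (relaxed vesicles) are session-scoped; every
simulation in the suite runs at desk scale (durations of tens to hundreds
of tau rather than the production 2e4 tau).
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import kinkvesicle as kv


@pytest.fixture(scope="session")
def params():
    return kv.SimulationParams(duration=10.0, seed=0)


@pytest.fixture(scope="session")
def wide_kink_vesicle():
    return kv.VesicleSpec(kink_angle=5 * math.pi / 6)


@pytest.fixture(scope="session")
def narrow_kink_vesicle():
    return kv.VesicleSpec(kink_angle=math.pi / 3)


@pytest.fixture(scope="session")
def wide_membrane(wide_kink_vesicle, params):
    return kv.build_vesicle(wide_kink_vesicle, params)


@pytest.fixture(scope="session")
def narrow_membrane(narrow_kink_vesicle, params):
    return kv.build_vesicle(narrow_kink_vesicle, params)


@pytest.fixture(scope="session")
def trimer():
    return kv.RodSpec(n_disks=3, peclet=75)


@pytest.fixture(scope="session")
def dimer():
    return kv.RodSpec(n_disks=2, peclet=75)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def packed_run_state(wide_membrane, wide_kink_vesicle, trimer, params):
    """A small rod-filled vesicle used by several dynamics tests."""
    return kv.place_rods(wide_membrane, trimer, 0.05, rng=7)
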