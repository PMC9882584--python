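"""Shared fixtures: linearization tables, trains and reference tissues.

The session-scoped linearization table covers flip angles up to pi and
dimensionless pulse durations trf*R2s in [5, 200], i.e. every pulse the
tests simulate; building it once keeps the suite fast without caching
anything on disk.
"""

import numpy as np
import pytest

from hybridmt.generalized_bloch import Lineshape, build_linearization_table
from hybridmt.mt_model import SystemParameters, TissueParameters
from hybridmt.sequence import default_train


@pytest.fixture(scope="session")
def table():
    return build_linearization_table(
        np.linspace(0.01, np.pi, 12), np.geomspace(5.0, 200.0, 10)
    )


@pytest.fixture(scope="session")
def super_lorentzian():
    return Lineshape("super_lorentzian", 10e-6)


@pytest.fixture(scope="session")
def wm_tissue():
    """Healthy white-matter means (m0s, T1f=1.84 s, T2f=76.9 ms, Rx=13.6/s,
    T1s=0.34 s, T2s=12.5 us) expressed as rates."""
    return TissueParameters(
        m0s=0.212,
        R1f=1 / 1.84,
        R2f=1 / 0.0769,
        Rx=13.6,
        R1s=1 / 0.34,
        T2s=12.5e-6,
    )


@pytest.fixture(scope="session")
def system():
    return SystemParameters()


@pytest.fixture(scope="session")
def train100():
    return default_train(100, seed=7)


@pytest.fixture(scope="session")
def train150():
    return default_train(150, seed=3)
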