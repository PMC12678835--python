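"""Shared fixtures: synthetic tips, materials and curve factories."""

import numpy as np
import pytest

from afmindent.calibration import TipProfile
from afmindent.config import CalibrationConfig
from afmindent.synthetic import IndenterTruth, MaterialTruth

E_STAR_REF = 3.79e6

# pure power-law tip used for calibration round trips (n = 2.5)
PL_C = 2.0e-9 / (60e-9) ** 2.5
PL_N = 2.5


@pytest.fixture
def config():
    return CalibrationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def paraboloid_tip():
    return IndenterTruth(kind="paraboloid", R=50e-9)


@pytest.fixture
def power_law_tip():
    return IndenterTruth(kind="power_law", c=PL_C, n=PL_N)


@pytest.fixture
def cone_tip():
    """Sharp cone truth, well-behaved for elastoplastic recovery."""
    return IndenterTruth(kind="polynomial", coeffs=np.array([0.0, 0.3]))


@pytest.fixture
def cone_tip_profile():
    return TipProfile.from_polynomial([0.0, 0.3], h_c_min=0.0, h_c_max=1e-5)


@pytest.fixture
def cell_truth():
    return MaterialTruth(behaviour="elastoplastic", E=1e9, nu=0.4, H=150e6)


@pytest.fixture
def visco_truth():
    return MaterialTruth(
        behaviour="viscoplastic",
        E=1.18e9,
        nu=0.4,
        C0=151e6,
        C1=30e6,
        C2=17e6,
        tau1=0.12,
        tau2=1.99,
    )
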