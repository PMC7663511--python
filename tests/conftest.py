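"""Shared fixtures: reference parameter sets and reusable geometries."""
import numpy as np
import pytest

from nanosorb.cnt import build_zigzag, NanotubeSpec
from nanosorb.constants import SAMPLING_TIMES_MIN


@pytest.fixture(scope="session")
def pristine_isotherm_params():
    """Published fit parameters for the unmodified-nanotube system, used as
    generating values for round-trip tests."""
    return {
        "freundlich": {"kF": 64.99, "1/n": 0.1725},
        "langmuir": {"qmax": 185.2, "KL": 0.0492},
        "temkin": {"b": 0.104, "kT": 4.70},
    }


@pytest.fixture(scope="session")
def modified_temkin_params():
    """Published Temkin parameters for the acid-treated system."""
    return {"b": 0.00165, "kT": 0.0464}


@pytest.fixture(scope="session")
def kinetic_params():
    """Published kinetic-model parameters (oxidized-system uptake)."""
    return {
        "pseudo_first": {"qe": 2290.0, "k1": 0.0110},
        "pseudo_second": {"qe": 4029.0, "k2": 6.92e-5},
        "intraparticle": {"k1": 1058.6, "C1": 82.59, "k2": 77.12, "C2": 317.0},
        "fractional_power": {"KFP": 1264.4, "v": 0.283},
        "elovich": {"alpha": 4136.2, "beta": 0.001537},
    }


@pytest.fixture(scope="session")
def sampling_times():
    return np.asarray(SAMPLING_TIMES_MIN)


@pytest.fixture(scope="session")
def swcnt_wall():
    """The n=82 single wall (6.42 nm) centred in the default box."""
    return build_zigzag(NanotubeSpec(chirality_n=82, origin=(10.0, 40.0, 10.0)))


@pytest.fixture(scope="session")
def small_wall():
    """A cheap n=12 tube (local z axis) for geometry checks that do not
    need study scale."""
    return build_zigzag(NanotubeSpec(chirality_n=12, length=2.0, axis=(0, 0, 1)))
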