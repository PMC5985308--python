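import numpy as np
import pytest

import wshort as w


@pytest.fixture(scope="session")
def wisc4():
    """Synthetic WISC-IV-like battery (10 subtests, FSIQ + GAI)."""
    return w.wisc_like_battery("IV", seed=0)


@pytest.fixture(scope="session")
def wisc5():
    return w.wisc_like_battery("V", seed=1)


@pytest.fixture(scope="session")
def loadings4(wisc4):
    return w.estimate_general_loadings(wisc4)


@pytest.fixture(scope="session")
def pop200k(wisc4):
    """Shared 200k-case simulated population."""
    return w.simulate_population(wisc4, n=200_000, seed=42)


@pytest.fixture(scope="session")
def two_group(wisc4):
    return w.generate_two_group_sample(wisc4, 117, 52, seed=7)


@pytest.fixture()
def tiny_battery_dict():
    """Minimal 4-subtest battery as a config document."""
    return {
        "name": "tiny",
        "subtests": [
            {"name": "Si", "index": "VCI", "reliability": 0.90},
            {"name": "Vo", "index": "VCI", "reliability": 0.89},
            {"name": "Bd", "index": "PRI", "reliability": 0.86},
            {"name": "Mr", "index": "PRI", "reliability": 0.88},
        ],
        "correlation": [
            [1.0, 0.60, 0.40, 0.38],
            [0.60, 1.0, 0.42, 0.41],
            [0.40, 0.42, 1.0, 0.55],
            [0.38, 0.41, 0.55, 1.0],
        ],
        "composites": {"FSIQ": ["Si", "Vo", "Bd", "Mr"], "GAI": ["Si", "Mr"]},
        "pools": {"verbal": ["Si", "Vo"], "performance": ["Bd", "Mr"]},
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
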