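import warnings

import numpy as np
import pytest

from hiernorm.config import default_config, build_circuit
from hiernorm.dynamics import solve_fixed_point, two_area
from hiernorm.network import RingGeometry, Stimulus, input_drive
from hiernorm.noise import NoiseSpec, build_stochastic_system
from hiernorm.params import ParameterRangeWarning

warnings.simplefilter("ignore", ParameterRangeWarning)


def small_config(n=16):
    cfg = default_config()
    cfg["circuit"]["n_neurons"] = n
    return cfg


@pytest.fixture(scope="session")
def geometry16():
    return RingGeometry(16)


@pytest.fixture(scope="session")
def small_spec():
    """Default-calibration two-area hierarchy on a 16-neuron ring."""
    spec, _ = build_circuit(small_config(16))
    return spec


@pytest.fixture(scope="session")
def small_drive(small_spec):
    g = small_spec.areas[0].geometry
    return {"V1": input_drive(Stimulus(50.0, 90.0), g, 40.0)}


@pytest.fixture(scope="session")
def small_fixed_point(small_spec, small_drive):
    return solve_fixed_point(small_spec, small_drive)


@pytest.fixture(scope="session")
def small_system(small_spec, small_drive, small_fixed_point):
    return build_stochastic_system(
        small_spec, small_fixed_point, NoiseSpec(), small_drive
    )


@pytest.fixture(scope="session")
def tiny_system():
    """8-neuron two-area system at 50% contrast, for heavier linear algebra."""
    cfg = small_config(8)
    spec, noise = build_circuit(cfg)
    g = spec.areas[0].geometry
    z = {"V1": input_drive(Stimulus(50.0, 90.0), g, 40.0)}
    st = solve_fixed_point(spec, z)
    return build_stochastic_system(spec, st, noise, z)
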