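import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fiberprobe as fp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: reported control-population mean parameters, used as the reference fiber
MEAN_PARAMS = dict(T0=7.44, k1=3.23, k2=10.94, eta=7.85)


@pytest.fixture(scope="session")
def geometry():
    return fp.FiberGeometry(28.4)


@pytest.fixture(scope="session")
def probe():
    return fp.CantileverProbe(3.0)


@pytest.fixture(scope="session")
def mean_params():
    return fp.MechanicalParams(**MEAN_PARAMS)


@pytest.fixture(scope="session")
def protocol():
    return fp.StageProtocol(v0=5.0, delta_s_star=20.0, t_hold=10.0, sample_rate=50.0)


@pytest.fixture(scope="session")
def reference_sim(geometry, probe, mean_params, protocol):
    """One forward simulation of the mean-parameter fiber, shared by many tests."""
    return fp.forward_simulate(geometry, probe, mean_params, protocol)


@pytest.fixture(scope="session")
def reference_trace(reference_sim):
    return fp.ExperimentTrace.from_sim(reference_sim)


@pytest.fixture(scope="session")
def reference_fit(reference_trace):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fp.fit_experiment(reference_trace)


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
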