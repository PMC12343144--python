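import numpy as np
import pytest

from endoimmune.classify import classify_attachment
from endoimmune.fixtures import DEFAULTS, get_fixture
from endoimmune.model_core import InfluxMode, ParameterSet, STATE_VARS
from endoimmune.simulate import Trajectory, run_study


@pytest.fixture(scope="session")
def reference():
    return get_fixture("reference")


@pytest.fixture(scope="session")
def bistable():
    return get_fixture("bistable")


@pytest.fixture(scope="session")
def diseased():
    return get_fixture("diseased")


@pytest.fixture(scope="session")
def reference_traj(reference):
    """Ten-cycle cyclic study under the reference parameters (shared)."""
    return run_study(reference, n_cycles=10)


@pytest.fixture(scope="session")
def reference_report(reference_traj):
    return classify_attachment(reference_traj)


def random_params(rng: np.random.Generator) -> ParameterSet:
    """A random valid parameter set: each rate/capacity scattered around its
    default by up to a factor of ~3, proportions uniform in (0, 1)."""
    d = {}
    for k, v in DEFAULTS.items():
        if k in ("rho_0", "gamma"):
            d[k] = float(rng.uniform(0.0, 1.0))
        elif k == "cycle_length":
            d[k] = 28.0
        elif k == "b_E":
            d[k] = float(rng.uniform(1.0, 24.0))
        elif k == "d_E":
            d[k] = float(rng.uniform(0.0, 28.0))
        else:
            d[k] = float(v * np.exp(rng.uniform(-1.2, 1.2)))
    return ParameterSet(**d)


def random_state(rng: np.random.Generator) -> np.ndarray:
    """A random non-negative state spanning several orders of magnitude."""
    return 10.0 ** rng.uniform(-2, 6, size=len(STATE_VARS))


def synthetic_trajectory(times, EA, M0=1.0, cycle_length=28.0):
    """A hand-built trajectory with prescribed EA and constant macrophages
    (for classifier tests that do not require a model solution)."""
    times = np.asarray(times, dtype=float)
    EA = np.asarray(EA, dtype=float)
    states = np.zeros((times.size, len(STATE_VARS)))
    states[:, 0] = M0
    states[:, 7] = EA
    return Trajectory(
        times=times,
        states=states,
        mode=InfluxMode.cyclic(),
        params_hash="synthetic",
        cycle_length=cycle_length,
    )
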