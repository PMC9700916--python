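import numpy as np
import pytest

import grnlink as gl


@pytest.fixture(scope="session")
def table1():
    return gl.make_preset_circuit("table1_ifl")


@pytest.fixture(scope="session")
def table1_fit(table1):
    """Hill model, trained synthesis network and normalized training series.

    One shared training run on noiseless step-perturbation data from the
    three-gene reference circuit; several tests inspect different aspects of
    the same fit.
    """
    cfg = gl.GeneratorConfig(seed=100, preset="table1_ifl", dt=1.0, n_timepoints=31)
    series = gl.generate_timeseries(table1, cfg)
    model, report, scaled = gl.fit_dynamics(series, epochs=2000, rng_seed=0)
    return table1, model, report, scaled


@pytest.fixture(scope="session")
def adapting_fit():
    """Trained network on the genuinely adapting minimal feed-forward circuit."""
    hill = gl.make_preset_circuit("adapting_ifl")
    cfg = gl.GeneratorConfig(seed=5, preset="adapting_ifl")
    series = gl.generate_timeseries(hill, cfg)
    model, report, scaled = gl.fit_dynamics(series, epochs=2000, rng_seed=1)
    return hill, model, report, scaled


@pytest.fixture
def iffl_topology():
    topo = np.zeros((3, 3), dtype=int)
    topo[0, 1] = 1  # input activates the intermediate
    topo[0, 2] = 1  # input activates the output
    topo[1, 2] = -1  # intermediate represses the output
    return topo
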