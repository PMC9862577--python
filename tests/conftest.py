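import numpy as np
import pytest

import foragemetrics as fm


@pytest.fixture(scope="session")
def small_config():
    """Short multi-dive trips, full sensor suite."""
    return fm.SimConfig(n_individuals=3, days_per_individual=0.12, seed=7)


@pytest.fixture(scope="session")
def trip(small_config):
    return fm.simulate_trip(small_config, 0)


@pytest.fixture(scope="session")
def pipeline(small_config):
    """Full pipeline output for three short trips."""
    trips = [fm.simulate_trip(small_config, i)
             for i in range(small_config.n_individuals)]
    data = fm.build_dataset(trips)
    data["trips"] = trips
    return data


def make_depth(depths, dt=1.0, t0=0.0):
    """DepthSeries from a plain list, 1 Hz by default."""
    depths = np.asarray(depths, dtype=float)
    return fm.DepthSeries(t0 + np.arange(depths.size) * dt, depths)
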