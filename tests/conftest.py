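import numpy as np
import pytest

from p53pulse.signal_core import Trace
from p53pulse.stats_report import build_feature_table
from p53pulse.synthdata import SimConfig, simulate_population


@pytest.fixture(scope="session")
def grid_120h():
    """Standard 120 h recording grid sampled every 0.5 h."""
    return np.arange(0.0, 120.0, 0.5)


def make_trace(y, t=None, cell_id="c0", channel="p53"):
    if t is None:
        t = np.arange(0.0, 0.5 * len(y), 0.5)
    return Trace(cell_id, channel, t, np.asarray(y, dtype=float))


@pytest.fixture(scope="session")
def small_population():
    """25 cells per dose, default scenario-2 conditions, fixed seed."""
    config = SimConfig(n_cells=25, seed=42)
    traces, divisions, metadata, truth = simulate_population(config)
    return config, traces, divisions, metadata, truth


@pytest.fixture(scope="session")
def small_features(small_population):
    """Feature table + p53 period ridges of the small population."""
    _, traces, divisions, metadata, truth = small_population
    features, ridges = build_feature_table(traces, divisions, metadata)
    return features, ridges, truth
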