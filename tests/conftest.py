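import numpy as np
import pytest

from switchssm.io import Track
from switchssm.model_core import ProcessParams, build_transition_matrix
from switchssm.simulator import simulate_scenario, table_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20160208)


@pytest.fixture
def large_contrast_params():
    """Reference large-contrast parameter set (gamma 0.95/0.10, theta 0/pi)."""
    return ProcessParams(
        gamma=(0.95, 0.10),
        theta=(0.0, np.pi),
        sigma=np.eye(2) * 25.0,
        alpha=build_transition_matrix(0.90, 0.10),
    )


def tracks_from_simulated(sim_tracks):
    return [
        Track(ident=t.track_id, times=t.times, y=t.y, lc=t.lc) for t in sim_tracks
    ]


@pytest.fixture
def errorfree_tracks():
    """Three error-free large-contrast tracks of 80 hourly steps."""
    scen = table_scenario("large", "none", n_tracks=3, track_length=80, seed=11)
    sim = simulate_scenario(scen)
    return sim, tracks_from_simulated(sim), scen
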