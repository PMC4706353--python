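import numpy as np
import pytest

from phaselock import (
    NetworkPairConfig,
    OscillatorPairConfig,
    simulate_phase_pair,
    simulate_ping_pair,
    synthesize_signals,
)


@pytest.fixture(scope="session")
def partial_sync_traj():
    """Noiseless partially synchronized pair (40 vs 43 Hz, kappa = 1)."""
    cfg = OscillatorPairConfig(
        omega_x=40.0, omega_y=43.0, kappa=1.0, n_trials=200, seed=5
    )
    return cfg, simulate_phase_pair(cfg)


@pytest.fixture(scope="session")
def partial_sync_signals(partial_sync_traj):
    cfg, traj = partial_sync_traj
    return cfg, traj, synthesize_signals(traj, cfg)


@pytest.fixture(scope="session")
def uncoupled_pram_signals():
    """Uncoupled pair at 3 Hz detuning with 20% PrAM on Y."""
    cfg = OscillatorPairConfig(
        omega_x=40.0, omega_y=43.0, kappa=0.0, pram_alpha=0.2,
        n_trials=200, seed=5,
    )
    traj = simulate_phase_pair(cfg)
    return cfg, traj, synthesize_signals(traj, cfg)


@pytest.fixture(scope="session")
def small_ping():
    """One short default-parameter PING pair shared across network tests."""
    cfg = NetworkPairConfig(n_trials=6, seed=3)
    rast_x, rast_y = simulate_ping_pair(cfg)
    return cfg, rast_x, rast_y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
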