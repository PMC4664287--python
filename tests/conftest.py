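import numpy as np
import pytest

from kinosc.model import (
    ModelParameters,
    SimulationConfig,
    fig1b_parameters,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def fig1b() -> ModelParameters:
    return fig1b_parameters()


@pytest.fixture(scope="session")
def sim_medium(fig1b):
    """A 300-frame simulation at the printed generative settings."""
    traj, states = simulate_trajectory(
        SimulationConfig(params=fig1b, n_frames=300, seed=3)
    )
    return traj, states


@pytest.fixture(scope="session")
def sim_noise_free(fig1b):
    """Exactly noise-free trajectory (pure drift integration), known states."""
    from dataclasses import replace

    from kinosc.model import Trajectory, drift_displacement, simulate_states

    params = replace(fig1b, tau=1e12)
    n = 120
    states = simulate_states(params.p_c, params.p_ic, n - 1, seed=7)
    x1, x2 = [params.L / 2], [-params.L / 2]
    for i in range(n - 1):
        d1, d2 = drift_displacement(
            params,
            "+" if states.sigma[i, 0] > 0 else "-",
            "+" if states.sigma[i, 1] > 0 else "-",
            x1[-1],
            x2[-1],
            0.0,
            2.0,
        )
        x1.append(x1[-1] + d1)
        x2.append(x2[-1] + d2)
    traj = Trajectory(x1=np.array(x1), x2=np.array(x2), dt=2.0)
    return traj, states, params


@pytest.fixture(scope="session")
def sim_pure_noise():
    """Brownian displacements: all drift parameters zero-like."""
    rng = np.random.default_rng(11)
    n = 200
    dt = 2.0
    sd = dt / np.sqrt(500.0)
    x1 = 0.5 + np.cumsum(rng.normal(0, sd, n))
    x2 = -0.5 + np.cumsum(rng.normal(0, sd, n))
    from kinosc.model import Trajectory

    x1 = x1 - x1.mean() + 0.5
    x2 = x2 - x2.mean() - 0.5
    return Trajectory(x1=x1, x2=x2, dt=dt, pair_id="bm-0")


@pytest.fixture(scope="session")
def fitted_medium(sim_medium):
    """A converged 2-chain fit of the 300-frame simulation."""
    from kinosc.mcmc import MCMCConfig, PriorSpec, run_mcmc

    traj, _ = sim_medium
    prior = PriorSpec().with_informed_L(0.8, 0.11)
    post, report = run_mcmc(
        traj, prior, MCMCConfig(n_sweeps=1500, n_chains=2), seed=5
    )
    return traj, post, report, prior
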