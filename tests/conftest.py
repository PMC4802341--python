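"""Shared fixtures: small seeded simulations reused across test modules.

Everything is generated at run time; session scope keeps each expensive
trajectory to a single integration.
"""
import numpy as np
import pytest

from activegcn.gcn_sim import SimConfig, run_simulation
from activegcn.potentials import BoxSpec, PairPotentialSpec


@pytest.fixture(scope="session")
def inv12():
    return PairPotentialSpec(form="inverse_power_12")


@pytest.fixture(scope="session")
def two_particle_traj():
    """Two x^-12 particles, D=tau=1, L=8; 6000 samples tau/2 apart."""
    cfg = SimConfig(N=2, L=8.0, D=1.0, tau=1.0, dt=1e-4, seed=31,
                    n_sample_steps=6000 * 5000, sample_interval=5000)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def many_body_traj():
    """N=100 x^-12 particles at rho=0.25, D=tau=1; 5000 samples."""
    cfg = SimConfig(N=100, rho=0.25, D=1.0, tau=1.0, dt=1e-4, seed=5,
                    n_sample_steps=5000 * 5000, sample_interval=5000)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def dense_traj():
    """N=100 at rho=0.5, D=tau=1; 600 decorrelated configurations."""
    cfg = SimConfig(N=100, rho=0.5, D=1.0, tau=1.0, dt=1e-4, seed=6,
                    n_sample_steps=600 * 5000, sample_interval=5000)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def ideal_gas_traj():
    """Synthetic ideal-gas trajectory: iid uniform positions, iid normal
    velocities with variance D/tau (no dynamics needed for estimator checks)."""
    from activegcn.gcn_sim import Trajectory

    g = np.random.default_rng(77)
    S, N, L, D, tau = 400, 100, 400.0, 1.0, 1.0
    cfg = SimConfig(N=N, L=L, D=D, tau=tau, dt=1e-3, seed=77,
                    potential=PairPotentialSpec(form="none"),
                    n_sample_steps=500, sample_interval=1)
    x = g.uniform(0, L, (S, N))
    v = g.normal(0, np.sqrt(D / tau), (S, N))
    return Trajectory(times=np.arange(S, dtype=float), positions=x,
                      noises=v.copy(), velocities=v, config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
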