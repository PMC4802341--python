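"""Simulation of interacting particles driven by Gaussian colored noise.

The model: overdamped particles in a 1-d periodic box,

    dx/dt = -grad phi(x) + eta,      tau * d eta/dt = -eta + sqrt(2 D) xi,

where eta is a vector of independent Ornstein-Uhlenbeck processes with zero
mean and correlator (D/tau) exp(-|t-t'|/tau).  D is the free-particle
diffusivity and tau the persistence time of the propulsion.

Positions advance by Euler-Maruyama; the noise uses the exact exponential
OU update, which is unbiased for any step size.  The recorded velocity is
always the integrator's own v = -grad phi(x) + eta, never a finite
difference of positions.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .potentials import (BoxSpec, DegenerateConfigurationError,
                         PairPotentialSpec, inverse_power_12, total_gradient)

__all__ = [
    "SimConfig",
    "SystemState",
    "Trajectory",
    "ExternalPotential",
    "ou_step",
    "langevin_step",
    "run_simulation",
    "StiffnessError",
]

# noise is generated in blocks of this many steps (fixed: part of the
# determinism contract — the PCG64 stream is consumed identically every run)
_BLOCK_STEPS = 4096


class StiffnessError(RuntimeError):
    """Per-step displacement exceeded the stability floor: reduce dt."""


@dataclass(frozen=True)
class ExternalPotential:
    """One-body power-law potential A * x**p (e.g. x^2, x^4, x^-12 barriers)."""

    amplitude: float = 1.0
    exponent: float = 2.0

    def value(self, x):
        return self.amplitude * np.asarray(x, float) ** self.exponent

    def deriv(self, x):
        return self.amplitude * self.exponent * np.asarray(x, float) ** (self.exponent - 1.0)

    def second_deriv(self, x):
        p = self.exponent
        return self.amplitude * p * (p - 1.0) * np.asarray(x, float) ** (p - 2.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulation run (reduced units).

    Either ``rho`` or ``L`` must be given; the other is derived as rho = N/L.
    ``sample_interval`` is in integrator steps; the default is chosen at
    construction so that successive samples are tau/2 apart.
    """

    N: int = 2
    D: float = 1.0
    tau: float = 1.0
    rho: Optional[float] = None
    L: Optional[float] = None
    dt: float = 1e-4
    n_equil_steps: Optional[int] = None
    n_sample_steps: Optional[int] = None
    sample_interval: Optional[int] = None
    seed: int = 0
    potential: PairPotentialSpec = field(default_factory=inverse_power_12)
    external: Optional[ExternalPotential] = None
    jitter: float = 0.05

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.D <= 0 or self.tau <= 0:
            raise ValueError("D and tau must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > self.tau / 50:
            raise ValueError(
                f"dt={self.dt} too large for tau={self.tau}: require dt <= tau/50 "
                "so the propulsion is resolved (stiffness guidance)")
        if self.rho is None and self.L is None:
            raise ValueError("give either rho or L")
        if self.rho is not None and self.L is not None:
            if abs(self.rho * self.L - self.N) > 1e-9 * self.N:
                raise ValueError("rho, L and N are inconsistent (rho = N/L)")
        L = self.box_length
        if self.potential.form == "inverse_power_12" and self.N > 1:
            if self.N / L >= 1.5:
                raise ValueError("density too high for a hard-core-like x^-12 system")
        # fill derived defaults
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "rho", self.N / L)
        if self.sample_interval is None:
            object.__setattr__(self, "sample_interval",
                               max(1, int(round(self.tau / 2 / self.dt))))
        if self.n_equil_steps is None:
            object.__setattr__(self, "n_equil_steps",
                               int(round(10 * self.tau / self.dt)))
        if self.n_sample_steps is None:
            object.__setattr__(self, "n_sample_steps", 200 * self.sample_interval)

    @property
    def box_length(self) -> float:
        if self.L is not None:
            return float(self.L)
        return self.N / float(self.rho)

    @property
    def box(self) -> BoxSpec:
        return BoxSpec(length=self.box_length)

    @property
    def n_samples(self) -> int:
        return self.n_sample_steps // self.sample_interval


@dataclass
class SystemState:
    """Instantaneous state: positions, OU noises, velocities, time."""

    positions: np.ndarray
    noise: np.ndarray
    velocities: np.ndarray
    time: float


@dataclass
class Trajectory:
    """Time-ordered samples of a run, with full provenance (config + seed)."""

    times: np.ndarray        # (S,)
    positions: np.ndarray    # (S, N)
    noises: np.ndarray       # (S, N)
    velocities: np.ndarray   # (S, N)
    config: SimConfig
    n_pd_failures: int = 0   # bookkeeping slot used by theory post-processing

    def __len__(self):
        return self.times.shape[0]

    def state(self, i: int) -> SystemState:
        return SystemState(self.positions[i], self.noises[i],
                           self.velocities[i], float(self.times[i]))

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.times, self.positions, self.noises, self.velocities):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


def ou_step(eta, dt: float, D: float, tau: float, rng: np.random.Generator):
    """Exact Ornstein-Uhlenbeck update over a time dt.

    eta' = eta e^{-dt/tau} + xi sqrt((D/tau)(1 - e^{-2 dt/tau})), xi ~ N(0,1).
    Stationary distribution: independent N(0, D/tau) components.
    """
    if D <= 0 or tau <= 0:
        raise ValueError("D and tau must be positive")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    eta = np.asarray(eta, dtype=float)
    a = np.exp(-dt / tau)
    b = np.sqrt(D / tau * (1.0 - a * a))
    return a * eta + b * rng.standard_normal(eta.shape)


def _total_force(x, config: SimConfig):
    f = -total_gradient(x, config.potential, config.box)
    if config.external is not None:
        f = f - config.external.deriv(x)
    return f


def langevin_step(state: SystemState, config: SimConfig,
                  rng: np.random.Generator) -> SystemState:
    """One Euler-Maruyama step (reference implementation, any potential).

    The returned state's velocity is v = -grad phi + eta at its own positions.
    """
    x, eta = state.positions, state.noise
    f = _total_force(x, config)
    v = f + eta
    disp = config.dt * v
    _check_step(disp, config)
    xn = x + disp
    if config.external is None:  # box wrap only when the box is meaningful
        xn = np.mod(xn, config.box_length)
    etan = ou_step(eta, config.dt, config.D, config.tau, rng)
    fn = _total_force(xn, config)
    return SystemState(xn, etan, fn + etan, state.time + config.dt)


def _check_step(disp, config: SimConfig):
    floor = 0.5 * (config.box_length / config.N if config.N > 1 else 1.0)
    m = float(np.max(np.abs(disp)))
    if not np.isfinite(m):
        raise StiffnessError("non-finite displacement: configuration diverged")
    if m > floor:
        raise StiffnessError(
            f"per-step displacement {m:.3g} exceeds half the mean spacing "
            f"({floor:.3g}); reduce dt (currently {config.dt})")


def initial_state(config: SimConfig, rng: np.random.Generator) -> SystemState:
    """Equally spaced positions with small uniform jitter; eta stationary.

    For pure external-potential runs (no pair interaction) the box has no
    role: particles start jittered around the origin instead.
    """
    L, N = config.box_length, config.N
    if config.external is not None and config.potential.form == "none":
        x = rng.uniform(-0.5, 0.5, N)
    else:
        spacing = L / N
        x = (np.arange(N) + 0.5) * spacing
        x = x + config.jitter * spacing * rng.uniform(-1.0, 1.0, N)
        x = np.mod(x, L)
    eta = np.sqrt(config.D / config.tau) * rng.standard_normal(N)
    f = _total_force(x, config)
    return SystemState(x, eta, f + eta, 0.0)


def _run_python(config: SimConfig, rng: np.random.Generator) -> Trajectory:
    st = initial_state(config, rng)
    for _ in range(config.n_equil_steps):
        st = langevin_step(st, config, rng)
    S = config.n_samples
    times = np.empty(S)
    xs = np.empty((S, config.N))
    es = np.empty((S, config.N))
    vs = np.empty((S, config.N))
    i = 0
    for step in range(config.n_sample_steps):
        if step % config.sample_interval == 0 and i < S:
            times[i] = st.time
            xs[i] = st.positions
            es[i] = st.noise
            vs[i] = st.velocities
            i += 1
        st = langevin_step(st, config, rng)
    return Trajectory(times[:i], xs[:i], es[:i], vs[:i], config)


def _run_kernel(config: SimConfig, rng: np.random.Generator) -> Trajectory:
    N, L, dt = config.N, config.box_length, config.dt
    a = np.exp(-dt / config.tau)
    b = np.sqrt(config.D / config.tau * (1.0 - a * a))
    st = initial_state(config, rng)
    x = np.sort(st.positions.copy())  # sorted order for the neighbour window
    eta = st.noise.copy()
    S = config.n_samples
    out_x = np.empty((S, N))
    out_eta = np.empty((S, N))
    out_v = np.empty((S, N))
    pair = config.potential.form == "inverse_power_12" and N > 1
    if pair:
        rc = config.potential.cutoff
        # each ring neighbour must be visited once: cap at N//2 (the kernel
        # deduplicates the coinciding +-k neighbour at k = N/2 and for N = 2)
        window = max(1, min(N // 2, int(np.ceil(rc * N / L)) + 2))
    floor = 0.5 * (L / N if N > 1 else 1.0)

    def advance(nsteps, record, step0, isample):
        done = 0
        while done < nsteps:
            blk = min(_BLOCK_STEPS, nsteps - done)
            noise = rng.standard_normal((blk, N))
            se = config.sample_interval if record else nsteps + 1
            s0 = step0 + done if record else 1  # step 1: never records
            if pair:
                isample, maxd = _kernels.step_block_inv12(
                    x, eta, noise, L, rc, window, dt, a, b,
                    se, s0, out_x, out_eta, out_v, isample)
            else:
                amp = config.external.amplitude if config.external else 0.0
                expo = config.external.exponent if config.external else 2.0
                if config.external is None:
                    amp = 0.0
                isample, maxd = _kernels.step_block_powerlaw(
                    x, eta, noise, amp, expo, dt, a, b,
                    se, s0, out_x, out_eta, out_v, isample)
            if not np.isfinite(maxd) or maxd > floor:
                raise StiffnessError(
                    f"per-step displacement {maxd:.3g} exceeds the stability "
                    f"floor {floor:.3g}; reduce dt (currently {dt})")
            done += blk
        return isample

    advance(config.n_equil_steps, record=False, step0=0, isample=0)
    if pair and N > 2:
        # ring order must be conserved (diverging core): the wrapped gaps
        # around the ring sum to exactly L iff no particle tunnelled
        gaps = np.mod(np.roll(x, -1) - x, L)
        if not np.isclose(gaps.sum(), L, rtol=1e-9):
            raise StiffnessError("particle ordering violated; reduce dt")
    nrec = advance(config.n_sample_steps, record=True, step0=0, isample=0)
    times = config.n_equil_steps * dt + dt * config.sample_interval * np.arange(nrec)
    return Trajectory(times, out_x[:nrec], out_eta[:nrec], out_v[:nrec], config)


def run_simulation(config: SimConfig, backend: str = "auto") -> Trajectory:
    """Equilibrate and sample a trajectory.  Deterministic under fixed seed.

    backend "auto" uses the numba fast path for the x^-12 pair system and for
    power-law external potentials, and the generic python stepper otherwise.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    pair_fast = (config.potential.form == "inverse_power_12"
                 and config.external is None and config.N > 1)
    free_fast = config.potential.form == "none" or config.N == 1
    if backend == "python" or (backend == "auto" and not (pair_fast or free_fast)):
        return _run_python(config, rng)
    return _run_kernel(config, rng)
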