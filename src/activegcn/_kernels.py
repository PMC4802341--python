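"""Numba hot loops for the colored-noise Langevin integrator.

The kernels advance positions with Euler-Maruyama and the propulsion noise
with the exact exponential Ornstein-Uhlenbeck update.  Gaussian variates are
generated *outside* the kernels (numpy PCG64 stream) and passed in blocks, so
reproducibility is governed by the numpy seed alone.

The pair kernel exploits the 1-d geometry: with a diverging repulsive core the
particle ordering is conserved, so forces are summed over a fixed window of
sorted neighbours on each side (window chosen from cutoff * density).
"""
import numba
import numpy as np

__all__ = ["step_block_inv12", "step_block_powerlaw", "forces_inv12"]


@numba.njit(cache=True)
def forces_inv12(x, L, rc, window, out):
    """Forces -dPhi/dx_i for phi = eps * dx^-12 (eps=1), sorted-order window sum."""
    n = x.shape[0]
    half = 0.5 * L
    for i in range(n):
        f = 0.0
        xi = x[i]
        for k in range(1, window + 1):
            j1 = i + k
            if j1 >= n:
                j1 -= n
            j2 = i - k
            if j2 < 0:
                j2 += n
            f += _pair_force(xi, x[j1], L, half, rc)
            if j2 != j1:  # coincide when n is even and k == n/2 (and for n=2)
                f += _pair_force(xi, x[j2], L, half, rc)
        out[i] = f
    return out


@numba.njit(cache=True, inline="always")
def _pair_force(xi, xj, L, half, rc):
    # minimum image: positions live in [0, L), so one fold suffices
    dx = xi - xj
    if dx > half:
        dx -= L
    elif dx < -half:
        dx += L
    r = abs(dx)
    if r < rc and r > 0.0:
        inv = 1.0 / r
        inv2 = inv * inv
        inv4 = inv2 * inv2
        inv14 = inv4 * inv4 * inv4 * inv2
        # -phi'(r)*sgn(dx) = 12 r^-13 sgn(dx) = 12 dx r^-14
        return 12.0 * dx * inv14
    return 0.0


@numba.njit(cache=True)
def step_block_inv12(x, eta, noise, L, rc, window, dt, a_ou, b_ou,
                     sample_every, step0, out_x, out_eta, out_v, isample0):
    """Advance a block of steps; record samples every `sample_every` steps.

    Returns (next sample index, max per-step displacement over the block).
    A sample records the state *before* the step: positions, noise and the
    instantaneous velocity v = -grad phi(x) + eta evaluated at those positions.
    """
    n = x.shape[0]
    nsteps = noise.shape[0]
    isample = isample0
    maxdisp = 0.0
    f = np.empty(n)
    for s in range(nsteps):
        forces_inv12(x, L, rc, window, f)
        record = (step0 + s) % sample_every == 0
        if record and isample < out_x.shape[0]:
            for i in range(n):
                out_x[isample, i] = x[i]
                out_eta[isample, i] = eta[i]
                out_v[isample, i] = f[i] + eta[i]
            isample += 1
        for i in range(n):
            disp = dt * (f[i] + eta[i])
            ad = abs(disp)
            if ad > maxdisp:
                maxdisp = ad
            xi = x[i] + disp
            # wrap into [0, L)
            xi -= L * np.floor(xi / L)
            x[i] = xi
            eta[i] = a_ou * eta[i] + b_ou * noise[s, i]
    return isample, maxdisp


@numba.njit(cache=True)
def step_block_powerlaw(x, eta, noise, amp, expo, dt, a_ou, b_ou,
                        sample_every, step0, out_x, out_eta, out_v, isample0):
    """Single-particle (or independent-particle) external potential A*x^p."""
    n = x.shape[0]
    nsteps = noise.shape[0]
    isample = isample0
    maxdisp = 0.0
    for s in range(nsteps):
        record = (step0 + s) % sample_every == 0
        for i in range(n):
            f = -amp * expo * x[i] ** (expo - 1.0)
            v = f + eta[i]
            if record and isample < out_x.shape[0]:
                out_x[isample, i] = x[i]
                out_eta[isample, i] = eta[i]
                out_v[isample, i] = v
            disp = dt * v
            if abs(disp) > maxdisp:
                maxdisp = abs(disp)
            x[i] += disp
            eta[i] = a_ou * eta[i] + b_ou * noise[s, i]
        if record:
            isample += 1
    return isample, maxdisp
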