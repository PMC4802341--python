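"""Mean-field effective free energy, stability scan and density fluctuations.

Mapping the stationary configurational density onto a Boltzmann form with
effective temperature D gives, for a homogeneous 1-d system of density rho,
the free energy per unit length

    f(rho)/D = rho ln rho - rho  -  rho ln(1 - rho sigma)
               - rho ln(1 + tau phi2 rho)

i.e. ideal gas + Tonks hard-rod excess + the velocity-entropy term, the log
of the determinant of I + tau*Hessian evaluated at mean-field level.  The
velocity term is the only activity effect: it is attractive (lowers f where
the velocity distribution is narrow, i.e. at high density) but at most
cancels the ideal term, so f''(rho) stays positive everywhere and the model
never crosses a spinodal.  It does, however, enhance long-wavelength density
fluctuations, S(q -> 0) = D / (rho f''(rho)), which develop an interior
maximum in rho at large persistence length l = sqrt(D tau).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mucna import mean_field_phi2_force_balance

__all__ = [
    "MeanFieldModel",
    "mean_field_free_energy",
    "free_energy_curvature",
    "spinodal_scan",
    "predicted_density_fluctuations",
    "tonks_free_energy",
    "tonks_curvature",
]


def _phi2(D, tau, phi2):
    return mean_field_phi2_force_balance(D, tau) if phi2 is None else phi2


def _check_domain(rho, sigma):
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0) or np.any(rho * sigma >= 1):
        raise ValueError("require 0 < rho*sigma < 1")
    return rho


def tonks_free_energy(rho, D, sigma):
    """Passive 1-d hard-rod (Tonks) free energy per unit length:
    D [rho ln rho - rho - rho ln(1 - rho sigma)]."""
    rho = _check_domain(rho, sigma)
    return D * (rho * np.log(rho) - rho - rho * np.log1p(-rho * sigma))


def tonks_curvature(rho, D, sigma):
    """f'' of the Tonks gas: D [1/rho + sigma (2 - rho sigma)/(1-rho sigma)^2]."""
    rho = _check_domain(rho, sigma)
    s = sigma
    return D * (1.0 / rho + s * (2.0 - rho * s) / (1.0 - rho * s) ** 2)


def mean_field_free_energy(rho, D, tau, sigma=1.0, phi2=None,
                           _velocity_term_scale=1.0):
    """Mean-field free energy per unit length (see module docstring).

    phi2=None selects the force-balance closure tau*phi2 = 2 sqrt(D tau);
    pass tau=0 (or phi2=0) to recover the passive Tonks gas exactly.
    ``_velocity_term_scale`` is a test hook that rescales the velocity-entropy
    term (e.g. -1 flips its sign to exercise the spinodal detector).
    """
    rho = _check_domain(rho, sigma)
    if tau == 0:
        a = 0.0
    else:
        a = tau * _phi2(D, tau, phi2)
    f = tonks_free_energy(rho, D, sigma)
    return f - _velocity_term_scale * D * rho * np.log1p(a * rho)


def free_energy_curvature(rho, D, tau, sigma=1.0, phi2=None,
                          _velocity_term_scale=1.0):
    """Analytic f''(rho) of the mean-field free energy.

    d2/drho2 [rho ln(1 + a rho)] = a (2 + a rho) / (1 + a rho)^2 with
    a = tau phi2; validated against central differences in the test suite.
    """
    rho = _check_domain(rho, sigma)
    a = 0.0 if tau == 0 else tau * _phi2(D, tau, phi2)
    fpp = tonks_curvature(rho, D, sigma)
    vel = a * (2.0 + a * rho) / (1.0 + a * rho) ** 2
    return fpp - _velocity_term_scale * D * vel


@dataclass
class MeanFieldModel:
    """Convenience wrapper evaluating f and f'' on a density grid."""

    D: float
    tau: float
    sigma: float = 1.0
    phi2: float = None
    rho_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.02, 0.95, 200))

    @property
    def f(self):
        return mean_field_free_energy(self.rho_grid, self.D, self.tau,
                                      self.sigma, self.phi2)

    @property
    def fpp(self):
        return free_energy_curvature(self.rho_grid, self.D, self.tau,
                                     self.sigma, self.phi2)


def spinodal_scan(rho_grid=None, D_grid=None, tau_grid=None, sigma=1.0,
                  _velocity_term_scale=1.0):
    """Tabulate the sign of f'' over a (rho, D, tau) grid.

    Returns a dict with the grids, the f'' array of shape
    (len(rho), len(D), len(tau)), the list of unstable (f'' <= 0) index
    triples (expected: none), and the location/value of the minimal f''.
    """
    rho_grid = np.asarray(rho_grid if rho_grid is not None
                          else np.linspace(0.02, 0.98, 49) / sigma)
    D_grid = np.asarray(D_grid if D_grid is not None
                        else np.logspace(-2, 3, 11))
    tau_grid = np.asarray(tau_grid if tau_grid is not None
                          else np.logspace(-2, 2, 9))
    fpp = np.empty((rho_grid.size, D_grid.size, tau_grid.size))
    for j, D in enumerate(D_grid):
        for k, tau in enumerate(tau_grid):
            fpp[:, j, k] = free_energy_curvature(
                rho_grid, D, tau, sigma, _velocity_term_scale=_velocity_term_scale)
    unstable = np.argwhere(fpp <= 0)
    imin = np.unravel_index(np.argmin(fpp / np.reshape(D_grid, (1, -1, 1))),
                            fpp.shape)
    return {
        "rho": rho_grid, "D": D_grid, "tau": tau_grid, "fpp": fpp,
        "unstable_cells": [tuple(u) for u in unstable],
        "n_unstable": int(unstable.shape[0]),
        "min_fpp_location": {
            "rho": float(rho_grid[imin[0]]),
            "D": float(D_grid[imin[1]]),
            "tau": float(tau_grid[imin[2]]),
        },
        "min_fpp": float(fpp[imin]),
    }


def predicted_density_fluctuations(rho, D, tau, sigma=1.0, phi2=None):
    """Long-wavelength density-fluctuation amplitude S(q->0) = D/(rho f'').

    Normalized so the ideal gas (sigma=0, tau=0, where f'' = D/rho) gives
    exactly 1, matching the simulation-side normalization of
    :func:`activegcn.observables.density_mode_fluctuations`.
    """
    rho = np.asarray(rho, dtype=float)
    fpp = free_energy_curvature(rho, D, tau, max(sigma, 1e-300), phi2)
    if np.any(fpp <= 0):
        raise ValueError("f'' <= 0: fluctuation amplitude undefined")
    return D / (rho * fpp)
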