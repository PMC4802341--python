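"""Unified-colored-noise (MUCNA) predictions for velocity statistics.

Within the multidimensional unified colored noise approximation the
stationary configurational density of the colored-noise model is

    P(x)  propto  exp{ -(1/D) [ Phi(x) + (tau/2) |grad Phi|^2 ] } * ||I + tau H(x)||

with H the Hessian of the total potential Phi, and the velocity distribution
conditional on the positions is a centred multivariate Gaussian with
covariance

    Cov(v | x) = (D/tau) (I + tau H(x))^{-1}.

The approximation is valid where I + tau H is positive definite; elsewhere a
:class:`UcnaValidityError` is raised (never clamped).

Everything downstream of these two objects is a closed form or a quadrature:
single-particle and two-particle variances, the two-hard-active-sphere
formula, the mean-field large-N variance, the small-persistence-time
expansion through the pair distribution function, and the Watson-integral
result for the periodic harmonic chain.  All variances are reported in units
of the free-particle value D/tau (so the non-interacting gas gives 1).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate
from scipy.linalg import eigvalsh, solve

from .potentials import BoxSpec, PairPotentialSpec, total_gradient, \
    total_hessian, total_potential

__all__ = [
    "UcnaValidityError",
    "MucnaMatrix",
    "TheoryCurve",
    "mucna_matrix",
    "config_log_prob",
    "velocity_covariance",
    "single_particle_variance",
    "two_particle_conditional",
    "two_particle_weight",
    "two_particle_separation_pdf",
    "two_particle_overall_variance",
    "hard_sphere_variance",
    "mean_field_variance",
    "mean_field_phi2_force_balance",
    "small_tau_phi2",
    "small_tau_variance",
    "harmonic_variance",
    "ensemble_variance_from_positions",
    "peclet_number",
    "persistence_length",
]


class UcnaValidityError(ValueError):
    """I + tau*Hessian is not positive definite: the approximation breaks down."""


@dataclass
class MucnaMatrix:
    """M = I + tau * Hessian(Phi) at a configuration, with validity check."""

    matrix: np.ndarray
    positions: np.ndarray
    tau: float

    @property
    def is_positive_definite(self) -> bool:
        return bool(np.min(eigvalsh(self.matrix)) > 0)


@dataclass
class TheoryCurve:
    """A predicted curve: abscissa grid (rho or separation), values, method."""

    abscissa: np.ndarray
    values: np.ndarray
    method: str
    D: float = 1.0
    tau: float = 1.0


def mucna_matrix(positions, spec: PairPotentialSpec, box: BoxSpec,
                 tau: float) -> MucnaMatrix:
    x = np.asarray(positions, float)
    H = total_hessian(x, spec, box)
    return MucnaMatrix(np.eye(x.size) + tau * H, x, tau)


def config_log_prob(positions, spec: PairPotentialSpec, box: BoxSpec,
                    D: float, tau: float) -> float:
    """Unnormalized log of the stationary configurational density.

    log P = -(1/D) [Phi + (tau/2)|grad Phi|^2] + log ||I + tau H||.
    At tau -> 0 this is the equilibrium Boltzmann weight -Phi/D.
    """
    x = np.asarray(positions, float)
    phi = total_potential(x, spec, box)
    g = total_gradient(x, spec, box)
    M = mucna_matrix(x, spec, box, tau)
    lam = eigvalsh(M.matrix)
    if np.min(lam) <= 0:
        raise UcnaValidityError(
            f"I + tau*Hessian has min eigenvalue {np.min(lam):.3g} <= 0")
    return float(-(phi + 0.5 * tau * np.dot(g, g)) / D + np.sum(np.log(lam)))


def velocity_covariance(positions, spec: PairPotentialSpec, box: BoxSpec,
                        D: float, tau: float) -> np.ndarray:
    """Conditional velocity covariance (D/tau) (I + tau H)^{-1}."""
    M = mucna_matrix(positions, spec, box, tau)
    lam = eigvalsh(M.matrix)
    if np.min(lam) <= 0:
        raise UcnaValidityError(
            f"I + tau*Hessian has min eigenvalue {np.min(lam):.3g} <= 0")
    n = M.matrix.shape[0]
    return (D / tau) * solve(M.matrix, np.eye(n), assume_a="pos")


def single_particle_variance(x, external_second_deriv, D: float, tau: float):
    """Velocity variance (D/tau)/(1 + tau phi''(x)) for one particle in an
    external potential; decreases where the curvature is high.

    ``external_second_deriv`` is a callable phi''(x) or an array of curvature
    values matching ``x``.
    """
    x = np.asarray(x, dtype=float)
    d2 = external_second_deriv(x) if callable(external_second_deriv) \
        else np.asarray(external_second_deriv, float)
    denom = 1.0 + tau * d2
    if np.any(denom <= 0):
        raise UcnaValidityError("1 + tau*phi'' <= 0: approximation invalid")
    return (D / tau) / denom


def two_particle_conditional(dx, spec: PairPotentialSpec, D: float, tau: float):
    """Variance and cross-correlation of the two velocities at separation dx.

    variance     = (D/2tau) (1 + 1/(1 + 2 tau phi''(dx)))
    correlation  = (D/2tau) (1 - 1/(1 + 2 tau phi''(dx)))

    At large separation: (D/tau, 0).  At infinite curvature both tend to
    D/(2 tau), the mean squared speed of the pair's centre of mass.
    """
    dx = np.abs(np.asarray(dx, dtype=float))
    if np.any(dx == 0):
        raise ValueError("separation must be nonzero")
    _, _, d2 = spec.value_derivs(dx)
    denom = 1.0 + 2.0 * tau * d2
    if np.any(denom <= 0):
        raise UcnaValidityError("1 + 2 tau phi'' <= 0: approximation invalid")
    half = 0.5 * D / tau
    return half * (1.0 + 1.0 / denom), half * (1.0 - 1.0 / denom)


def two_particle_weight(dx, spec: PairPotentialSpec, D: float, tau: float):
    """Unnormalized stationary density of the pair separation,
    w(dx) = exp{-(phi + tau phi'^2)/D} (1 + 2 tau phi'')."""
    dx = np.abs(np.asarray(dx, dtype=float))
    v, d1, d2 = spec.value_derivs(dx)
    return np.exp(-(v + tau * d1 * d1) / D) * (1.0 + 2.0 * tau * d2)


def _quad_pair(f, spec: PairPotentialSpec, D: float, tau: float, hi: float):
    """Adaptive quadrature of f over (0, hi] skipping the numerically-dead
    core region; breakpoints bracket the contact peak of the weight."""
    # for the stiff x^-12 core the weight underflows to exactly 0 below 0.2
    # for every D <= 1e4; start there and bracket the contact peak
    lo = 0.2 if spec.form == "inverse_power_12" else 1e-9 * hi
    pts = [p for p in (0.7, 0.85, 1.0, 1.2, 1.6, 2.5) if lo < p < hi]
    val, _ = integrate.quad(f, lo, hi, points=pts or None, limit=400,
                            epsabs=1e-12, epsrel=1e-10)
    return val


def two_particle_separation_pdf(dx, rho: float, spec: PairPotentialSpec,
                                D: float, tau: float):
    """Normalized stationary pdf of the folded pair separation |dx| on
    (0, L/2], with L = 2/rho (two particles in a periodic box)."""
    L = 2.0 / rho
    Z = _quad_pair(lambda z: two_particle_weight(z, spec, D, tau),
                   spec, D, tau, L / 2)
    return two_particle_weight(dx, spec, D, tau) / Z


def two_particle_overall_variance(rho: float, spec: PairPotentialSpec,
                                  D: float, tau: float) -> float:
    """Position-averaged normalized velocity variance of the two-particle
    periodic system at 1-d density rho = 2/L (in units of D/tau).

    Quadrature of the conditional trace against the stationary separation
    density; -> 1 as rho -> 0 and decreases with rho and D.
    """
    if not rho > 0:
        raise ValueError("rho must be positive")
    L = 2.0 / rho

    def w(z):
        return two_particle_weight(z, spec, D, tau)

    def num(z):
        var, _ = two_particle_conditional(z, spec, D, tau)
        return w(z) * var * tau / D  # normalized conditional trace / dN

    Z = _quad_pair(w, spec, D, tau, L / 2)
    if not np.isfinite(Z) or Z <= 0:
        raise ArithmeticError("separation-density normalization failed")
    return _quad_pair(num, spec, D, tau, L / 2) / Z


def hard_sphere_variance(rho, D, tau, sigma: float = 1.0):
    """Two-active-hard-sphere closed form for the normalized variance.

    In the hard limit the separation density is uniform outside contact plus
    a Dirac peak of area sqrt(pi D tau) at |dx| = sigma where the conditional
    variance is D/(2 tau); elsewhere it is the free value D/tau:

        var / (D/tau) = [(1 - rho sigma) + (rho/2) sqrt(pi D tau)]
                        / [(1 - rho sigma) + rho sqrt(pi D tau)]

    Bounded below by 1/2 (attained jointly at large rho and D); depends on D
    only through rho sqrt(D tau) / (1 - rho sigma), i.e. through the
    persistence length l = sqrt(D tau).
    """
    rho = np.asarray(rho, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(rho * sigma >= 1):
        raise ValueError("rho*sigma must be < 1 (hard spheres overlap)")
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    a = np.sqrt(np.pi * D * tau) * rho
    free = 1.0 - rho * sigma
    return (free + 0.5 * a) / (free + a)


def peclet_number(D, tau, sigma: float = 1.0):
    """Persistence length over particle size, l/sigma = sqrt(D tau)/sigma."""
    return np.sqrt(D * tau) / sigma


def persistence_length(D, tau):
    return np.sqrt(D * tau)


def mean_field_phi2_force_balance(D: float, tau: float) -> float:
    """Force-balance closure: sigma is where |phi'(sigma)| equals the rms
    propulsion speed sqrt(D/tau); the (two-sided) curvature integral is then
    phi2 = 2|phi'(sigma)| = 2 sqrt(D/tau), so tau phi2 rho = 2 rho sqrt(D tau)."""
    return 2.0 * np.sqrt(D / tau)


def mean_field_variance(rho, D: float, tau: float, phi2: Optional[float] = None,
                        N: Optional[int] = None):
    """Mean-field (uniform density, long-range) normalized velocity variance.

    With phi2 the density-scaled mean pair curvature (two-sided integral,
    see :func:`small_tau_phi2`), the matrix I + tau H has (N-1) eigenvalues
    1 + (N+1) tau phi2 rho / N and one eigenvalue 1 + tau phi2 rho / N.

    large-N (default):   1 / (1 + tau phi2 rho)
    finite N:            [ (N-1)/(1 + (N+1) tau phi2 rho / N)
                           + 1/(1 + tau phi2 rho / N) ] / N

    If phi2 is None the force-balance closure is used, giving a variance that
    depends only on rho * sqrt(D tau).
    """
    rho = np.asarray(rho, dtype=float)
    if phi2 is None:
        phi2 = mean_field_phi2_force_balance(D, tau)
    a = tau * phi2 * rho
    if N is None:
        denom = 1.0 + a
        if np.any(denom <= 0):
            raise ValueError("1 + tau*phi2*rho must be positive")
        return 1.0 / denom
    d1 = 1.0 + (N + 1) * a / N
    d2 = 1.0 + a / N
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("mean-field eigenvalues must be positive")
    return ((N - 1) / d1 + 1.0 / d2) / N


def small_tau_phi2(g_centers, g_values=None, spec: PairPotentialSpec = None,
                   tau: float = 0.0) -> float:
    """Effective mean pair curvature from the pair distribution function.

    phi2 = integral_0^inf g(x) * 2 phi''(x) / (1 + 2 tau phi''(x)) dx

    (trapezoid on the g grid).  At tau = 0 this is the two-sided curvature
    integral 2*int g phi'' dx of the literal first-order-in-tau expansion of
    tr(I + tau H)^{-1}/N; the 1/(1 + 2 tau phi'') kernel resums the
    contribution of an isolated stiff pair (whose trace deficit is
    2 tau phi''/(1 + 2 tau phi''), never more than 1), which is what makes
    the expansion usable for a steep core where tau*phi'' is not small at
    the separations where g has weight.  Feeding the result to
    :func:`mean_field_variance` (or :func:`small_tau_variance`) gives the
    small-persistence-time variance curve.

    ``g_centers`` may be a :class:`~activegcn.observables.BinnedStat` (its bin
    centres and means are used) or a plain grid with ``g_values``.  The grid
    must cover the support of phi''; a coverage error is raised if the
    integrand is still appreciable at the last grid point.
    """
    if hasattr(g_centers, "centers") and g_values is None:
        x = np.asarray(g_centers.centers, float)
        g = np.asarray(g_centers.mean, float)
    else:
        x = np.asarray(g_centers, dtype=float)
        g = np.asarray(g_values, dtype=float)
    if x.ndim != 1 or x.shape != g.shape:
        raise ValueError("g grid and values must be matching 1-d arrays")
    if np.any(np.diff(x) <= 0):
        raise ValueError("g grid must be strictly increasing")
    if np.any(g < 0):
        raise ValueError("g must be non-negative")
    _, _, d2 = spec.value_derivs(np.maximum(x, 1e-12))
    cover = g * d2  # undamped integrand is the conservative coverage gauge
    peak = float(np.max(cover)) if cover.size else 0.0
    if peak > 0 and cover[-1] > 1e-3 * peak:
        raise ValueError(
            "g grid does not cover the support of phi'': the integrand is "
            f"still {cover[-1]/peak:.1%} of its peak at x={x[-1]:.3g}")
    integrand = g * 2.0 * d2 / (1.0 + 2.0 * tau * d2)
    return float(np.trapezoid(integrand, x))


def small_tau_variance(g, spec: PairPotentialSpec, rho: float, tau: float):
    """Small-persistence-time normalized variance from a measured g(x):
    1 - rho * tau * phi2, the additive trace deficit of dilute stiff pairs
    (phi2 from :func:`small_tau_phi2` with the same tau)."""
    phi2 = small_tau_phi2(g, spec=spec, tau=tau)
    val = 1.0 - rho * tau * phi2
    if val <= 0:
        raise ValueError("deficit exceeds 1: outside the small-tau regime")
    return val


def harmonic_variance(k, tau: float):
    """Normalized velocity variance of the periodic harmonic chain.

    Mean inverse eigenvalue of I + tau*H for the nearest-neighbour chain,
    a Watson integral with closed form

        (1/2pi) int_0^{2pi} dtheta / (1 + 2 tau k (1 - cos theta))
            = 1 / sqrt(1 + 4 tau k).

    With the high-density mapping k(rho) = 156 rho^14 of the x^-12 fluid this
    is the harmonic-model curve.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("spring constant must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return 1.0 / np.sqrt(1.0 + 4.0 * tau * k)


def effective_spring_constant(rho):
    """2nd-order expansion of x^-12 around the mean spacing: k = 156 rho^14."""
    return 156.0 * np.asarray(rho, dtype=float) ** 14


def ensemble_variance_from_positions(position_samples: Sequence[np.ndarray],
                                     spec: PairPotentialSpec, box: BoxSpec,
                                     D: float, tau: float):
    """Average of tr[(I + tau H)^{-1}]/N over sampled configurations.

    Returns ``(mean, stderr, n_invalid)`` where the mean is in units of D/tau
    (so the prediction for the simulated normalized velocity variance), the
    standard error is a delete-one jackknife over configurations, and
    ``n_invalid`` counts configurations whose MUCNA matrix was not positive
    definite (excluded from the average, never clamped).
    """
    samples = list(position_samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 configurations")
    vals = []
    n_invalid = 0
    for x in samples:
        x = np.asarray(x, float)
        M = np.eye(x.size) + tau * total_hessian(x, spec, box)
        lam = eigvalsh(M)
        if lam.min() <= 0:
            n_invalid += 1
            continue
        vals.append(np.mean(1.0 / lam))
    if not vals:
        raise UcnaValidityError("no configuration had a positive definite matrix")
    vals = np.asarray(vals)
    n = vals.size
    mean = vals.mean()
    if n > 1:
        jk = (vals.sum() - vals) / (n - 1)
        stderr = np.sqrt((n - 1) / n * np.sum((jk - jk.mean()) ** 2))
    else:
        stderr = np.nan
    return float(mean), float(stderr), n_invalid
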