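"""Pair potentials with analytic derivatives, and many-body force/Hessian assembly.

All energies are in reduced units (the energy scale of the pair potential and
the particle mobility are both 1).  Positions live in a periodic box and every
pairwise quantity uses the minimum-image separation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "PairPotentialSpec",
    "BoxSpec",
    "inverse_power_12",
    "harmonic_pair",
    "pair_value_derivs",
    "minimum_image",
    "total_potential",
    "total_gradient",
    "total_hessian",
    "harmonic_chain_hessian",
    "DegenerateConfigurationError",
]

#: default truncation radius for the x^-12 interaction; |phi'(4)| ~ 2e-7,
#: negligible against the propulsion speed sqrt(D/tau) in every studied regime.
DEFAULT_CUTOFF = 4.0


class DegenerateConfigurationError(ValueError):
    """Raised when particles coincide (pair separation is zero)."""


@dataclass(frozen=True)
class PairPotentialSpec:
    """A pair interaction with analytic value, first and second derivative.

    Parameters
    ----------
    form : {"inverse_power_12", "harmonic", "custom", "none"}
        ``inverse_power_12`` is the repulsive phi(x) = x^-12 of the model;
        ``harmonic`` is a spring phi(x) = (k/2) x^2; ``none`` means ideal gas.
    energy_scale : float
        Prefactor of the potential (reduced units, default 1).
    spring_k : float, optional
        Spring constant, harmonic form only.
    cutoff : float, optional
        Truncation radius (inverse-power only); value and derivatives are
        exactly zero beyond it.  Unshifted truncation.
    custom : tuple of callables, optional
        ``(value, deriv, second_deriv)`` for the custom form.
    """

    form: str = "inverse_power_12"
    energy_scale: float = 1.0
    spring_k: float = 1.0
    cutoff: float = DEFAULT_CUTOFF
    custom: Optional[tuple] = field(default=None, compare=False)

    def __post_init__(self):
        if self.form not in ("inverse_power_12", "harmonic", "custom", "none"):
            raise ValueError(f"unknown potential form {self.form!r}")
        if self.form == "inverse_power_12" and not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if self.form == "custom" and self.custom is None:
            raise ValueError("custom form requires (value, deriv, second_deriv) callables")

    # -- scalar evaluation ------------------------------------------------
    def value_derivs(self, r):
        """Return (phi(r), phi'(r), phi''(r)) at separation r > 0."""
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise DegenerateConfigurationError("pair separation must be positive")
        if self.form == "none":
            z = np.zeros_like(r)
            return z, z.copy(), z.copy()
        if self.form == "harmonic":
            k = self.energy_scale * self.spring_k
            return 0.5 * k * r * r, k * r, np.full_like(r, k)
        if self.form == "custom":
            v, d1, d2 = self.custom
            return (np.asarray(v(r), float), np.asarray(d1(r), float),
                    np.asarray(d2(r), float))
        # inverse power 12
        eps = self.energy_scale
        inside = r < self.cutoff
        inv = np.where(inside, 1.0 / np.where(inside, r, 1.0), 0.0)
        inv2 = inv * inv
        inv4 = inv2 * inv2
        inv12 = inv4 * inv4 * inv4
        v = eps * inv12
        d1 = -12.0 * eps * inv12 * inv
        d2 = 156.0 * eps * inv12 * inv2
        return v, d1, d2


def inverse_power_12(cutoff: float = DEFAULT_CUTOFF) -> PairPotentialSpec:
    return PairPotentialSpec(form="inverse_power_12", cutoff=cutoff)


def harmonic_pair(k: float) -> PairPotentialSpec:
    return PairPotentialSpec(form="harmonic", spring_k=k)


def pair_value_derivs(spec: PairPotentialSpec, r):
    """Functional alias for :meth:`PairPotentialSpec.value_derivs`."""
    return spec.value_derivs(r)


@dataclass(frozen=True)
class BoxSpec:
    """Periodic box of length L in d dimensions (d=1 supported)."""

    length: float
    dimension: int = 1
    periodic: bool = True

    def __post_init__(self):
        if not self.length > 0:
            raise ValueError("box length must be positive")
        if self.dimension != 1:
            raise NotImplementedError("only d=1 is implemented")
        if not self.periodic:
            raise ValueError("the box is always periodic")


def minimum_image(dx, L: float):
    """Fold separations into (-L/2, L/2]."""
    dx = np.asarray(dx, dtype=float)
    out = dx - L * np.round(dx / L)
    # np.round maps exactly -L/2 to -L/2 depending on parity; enforce (-L/2, L/2]
    out = np.where(out <= -L / 2, out + L, out)
    return out


def _pair_separations(positions, box: BoxSpec):
    x = np.asarray(positions, dtype=float)
    dx = minimum_image(x[:, None] - x[None, :], box.length)
    return dx


def total_potential(positions, spec: PairPotentialSpec, box: BoxSpec) -> float:
    """Total pair energy sum_{i<j} phi(|x_i - x_j|) with minimum image."""
    x = np.asarray(positions, dtype=float)
    n = x.size
    if n < 2 or spec.form == "none":
        return 0.0
    dx = _pair_separations(x, box)
    iu = np.triu_indices(n, 1)
    r = np.abs(dx[iu])
    if np.any(r == 0):
        raise DegenerateConfigurationError("coincident particles")
    v, _, _ = spec.value_derivs(r)
    return float(np.sum(v))


def total_gradient(positions, spec: PairPotentialSpec, box: BoxSpec):
    """Gradient of the total pair potential; component i is
    sum_{j != i} phi'(|x_i - x_j|) sgn(x_i - x_j)."""
    x = np.asarray(positions, dtype=float)
    n = x.size
    grad = np.zeros(n)
    if n < 2 or spec.form == "none":
        return grad
    dx = _pair_separations(x, box)
    r = np.abs(dx)
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] == 0):
        raise DegenerateConfigurationError("coincident particles")
    rs = np.where(off, r, 1.0)
    _, d1, _ = spec.value_derivs(rs)
    contrib = np.where(off, d1 * np.sign(dx), 0.0)
    return contrib.sum(axis=1)


def total_hessian(positions, spec: PairPotentialSpec, box: BoxSpec):
    """Hessian of the total pair potential (symmetric N x N, rows sum to 0)."""
    x = np.asarray(positions, dtype=float)
    n = x.size
    H = np.zeros((n, n))
    if n < 2 or spec.form == "none":
        return H
    dx = _pair_separations(x, box)
    r = np.abs(dx)
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] == 0):
        raise DegenerateConfigurationError("coincident particles")
    rs = np.where(off, r, 1.0)
    _, _, d2 = spec.value_derivs(rs)
    d2 = np.where(off, d2, 0.0)
    H = -d2
    np.fill_diagonal(H, d2.sum(axis=1))
    return H


def harmonic_chain_hessian(N: int, k: float):
    """Hessian of the periodic nearest-neighbour harmonic chain.

    Banded symmetric Toeplitz (circulant) matrix: 2k on the diagonal, -k on the
    first off-diagonals and the two wrap corners.  Eigenvalues are
    2k(1 - cos(2 pi m / N)), m = 0..N-1; the zero mode is uniform translation.
    """
    if N < 3:
        raise ValueError("periodic chain requires N >= 3")
    if k < 0:
        raise ValueError("spring constant must be non-negative")
    H = np.zeros((N, N))
    idx = np.arange(N)
    H[idx, idx] = 2.0 * k
    H[idx, (idx + 1) % N] = -k
    H[idx, (idx - 1) % N] = -k
    return H
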