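"""Estimators for the quantities measured on simulated trajectories.

Overall and conditional velocity statistics, the pair distribution function
g(x), the effective particle diameter, and single-mode Fourier density
fluctuations.  All velocity variances are normalized by the free-particle
value D/tau; density fluctuations are normalized so an ideal gas gives 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gcn_sim import Trajectory
from .potentials import minimum_image

__all__ = [
    "BinnedStat",
    "DensityModeResult",
    "overall_velocity_variance",
    "conditional_velocity_stats",
    "pair_distribution",
    "effective_diameter",
    "density_mode_fluctuations",
]


@dataclass
class BinnedStat:
    """Per-bin mean with counts and standard errors on a 1-d grid."""

    bin_edges: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    stderr: np.ndarray  # NaN where count < 2

    def __post_init__(self):
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class DensityModeResult:
    """Fluctuation of a single Fourier density mode.

    value = (<|rho_q|^2> - |<rho_q>|^2) / N over sampled configurations,
    which is exactly 1 for iid uniform positions (ideal gas).
    """

    q: float
    mode_index: int
    value: float
    stderr: float
    n_samples: int


def overall_velocity_variance(traj: Trajectory):
    """Normalized velocity variance and its configuration-to-configuration
    spread.

    Returns ``(value, stderr, rel_spread)``: the mean of v^2 over particles,
    components and samples divided by D/tau; the standard error over
    configurations; and the relative standard deviation of the
    per-configuration variances (the paper-style error estimate).
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 sampled configurations")
    per_config = np.mean(traj.velocities ** 2, axis=1)
    scale = traj.config.D / traj.config.tau
    value = float(per_config.mean() / scale)
    stderr = float(per_config.std(ddof=1) / np.sqrt(per_config.size) / scale)
    m = per_config.mean()
    rel_spread = float(per_config.std(ddof=1) / m) if m > 0 else float("nan")
    return value, stderr, rel_spread


def _binned(values_by_bin_idx, values, nbins):
    mean = np.full(nbins, np.nan)
    cnt = np.zeros(nbins, dtype=int)
    err = np.full(nbins, np.nan)
    for b in range(nbins):
        sel = values_by_bin_idx == b
        n = int(sel.sum())
        cnt[b] = n
        if n:
            mean[b] = values[sel].mean()
        if n >= 2:
            err[b] = values[sel].std(ddof=1) / np.sqrt(n)
    return mean, cnt, err


def conditional_velocity_stats(traj: Trajectory, bin_edges, n_blocks: int = 16):
    """Velocity variance and cross-correlation binned by pair separation,
    for a two-particle trajectory.

    Per bin of the minimum-image |x1 - x2| (parity symmetry doubles the
    statistics): the sample variance of a single particle's velocity (both
    particles pooled) and the sample covariance of the two velocities.
    Standard errors come from the spread of ``n_blocks`` contiguous time
    blocks, which accounts for the temporal correlation of successive
    samples.  Empty bins are flagged with NaN and count 0, never dropped.
    """
    if traj.positions.shape[1] != 2:
        raise ValueError("conditional statistics are defined for N=2 runs")
    edges = np.asarray(bin_edges, float)
    L = traj.config.box_length
    sep = np.abs(minimum_image(traj.positions[:, 0] - traj.positions[:, 1], L))
    idx = np.digitize(sep, edges) - 1
    ok = (idx >= 0) & (idx < edges.size - 1)
    v1, v2 = traj.velocities[:, 0], traj.velocities[:, 1]
    nbins = edges.size - 1
    # pooled point estimates (conditional mean velocity is 0 by symmetry)
    vv = 0.5 * (v1 ** 2 + v2 ** 2)
    var_mean, var_cnt, _ = _binned(idx[ok], vv[ok], nbins)
    cov_mean, cov_cnt, _ = _binned(idx[ok], (v1 * v2)[ok], nbins)
    var_cnt = 2 * var_cnt  # both particles contribute an observation

    def block_err(values):
        bounds = np.linspace(0, len(traj), n_blocks + 1).astype(int)
        means = np.full((n_blocks, nbins), np.nan)
        for b in range(n_blocks):
            sl = slice(bounds[b], bounds[b + 1])
            sel = ok[sl]
            m, c, _ = _binned(idx[sl][sel], values[sl][sel], nbins)
            means[b] = m
        err = np.full(nbins, np.nan)
        for j in range(nbins):
            col = means[:, j]
            col = col[np.isfinite(col)]
            if col.size >= 2:
                err[j] = col.std(ddof=1) / np.sqrt(col.size)
        return err

    var = BinnedStat(edges, var_mean, var_cnt, block_err(vv))
    cov = BinnedStat(edges, cov_mean, cov_cnt, block_err(v1 * v2))
    return var, cov


def pair_distribution(traj: Trajectory, bin_edges) -> BinnedStat:
    """1-d pair distribution function g(x) from minimum-image separations.

    Histogram of |x_i - x_j| over all pairs and samples, normalized so that
    an ideal gas gives g = 1: the expected ideal count per unordered pair and
    bin of width w is 2 w / L.
    """
    edges = np.asarray(bin_edges, float)
    L = traj.config.box_length
    n = traj.positions.shape[1]
    if n < 2:
        raise ValueError("pair distribution requires N >= 2")
    if edges[-1] > L / 2 + 1e-12:
        raise ValueError("bin range exceeds L/2 (minimum-image fold)")
    S = len(traj)
    counts = np.zeros(edges.size - 1)
    counts_sq = np.zeros(edges.size - 1)
    iu = np.triu_indices(n, 1)
    for s in range(S):
        x = traj.positions[s]
        r = np.abs(minimum_image(x[:, None] - x[None, :], L))[iu]
        c, _ = np.histogram(r, edges)
        counts += c
        counts_sq += c.astype(float) ** 2
    widths = np.diff(edges)
    norm = S * (n * (n - 1) / 2) * 2.0 * widths / L
    g = counts / norm
    # per-bin stderr from the spread of per-sample counts
    var_c = counts_sq / S - (counts / S) ** 2
    err = np.sqrt(np.maximum(var_c, 0.0) / S) * S / norm
    cnt = counts.astype(int)
    err = np.where(cnt >= 2, err, np.nan)
    return BinnedStat(edges, g, cnt, err)


def effective_diameter(g: BinnedStat, threshold_fraction: float = 0.05) -> float:
    """Effective particle diameter from g(x): the smallest bin centre where
    g first reaches ``threshold_fraction`` of its maximum, scanning outward
    from zero separation."""
    vals = np.nan_to_num(g.mean, nan=0.0)
    gmax = vals.max()
    if gmax <= 0:
        raise ValueError("g is identically zero: diameter undefined")
    thr = threshold_fraction * gmax
    idx = np.nonzero(vals >= thr)[0]
    return float(g.centers[idx[0]])


def density_mode_fluctuations(traj: Trajectory, m: int) -> DensityModeResult:
    """Fluctuation of the Fourier density mode q = 2 pi m / L.

    rho_q = sum_j exp(-i q x_j) per configuration;
    value = (<|rho_q|^2> - |<rho_q>|^2)/N with a naive standard error over
    samples (samples of long-wavelength modes are strongly correlated in
    time, so treat the error as a lower bound).
    """
    if m < 1:
        raise ValueError("mode index must be >= 1 (m=0 is the trivial mode)")
    if len(traj) < 2:
        raise ValueError("need at least 2 sampled configurations")
    L = traj.config.box_length
    N = traj.positions.shape[1]
    q = 2.0 * np.pi * m / L
    rq = np.exp(-1j * q * traj.positions).sum(axis=1)
    mod2 = np.abs(rq) ** 2
    value = (mod2.mean() - np.abs(rq.mean()) ** 2) / N
    stderr = mod2.std(ddof=1) / np.sqrt(mod2.size) / N
    return DensityModeResult(q=q, mode_index=m, value=float(value),
                             stderr=float(stderr), n_samples=len(traj))


def nearest_mode_index(L: float, q_target: float) -> int:
    """Allowed box mode 2 pi m / L closest to q_target, with m >= 1."""
    return max(1, int(round(q_target * L / (2.0 * np.pi))))
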