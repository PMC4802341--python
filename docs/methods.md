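# Methods

## The model

`activegcn` simulates and analyses overdamped self-propelled particles whose
propulsion is Gaussian colored noise. In one dimension, with particle
mobility set to 1,

    dx_i/dt  = -∂Φ/∂x_i + η_i,
    τ dη_i/dt = -η_i + √(2D) ξ_i(t),

where Φ is the total interaction potential, the η_i are independent
Ornstein–Uhlenbeck processes with ⟨η_i(t) η_j(t′)⟩ = δ_ij (D/τ) e^{−|t−t′|/τ},
D is the free-particle diffusivity and τ the persistence time of the
propulsion. The persistence length ℓ = √(Dτ) measured against the particle
size σ plays the role of a Péclet number. Particles interact through the
steep repulsion φ(Δx) = Δx⁻¹² (effective diameter σ ≈ 1 in reduced units) or
through nearest-neighbour harmonic springs; a periodic box of length L sets
the density ρ = N/L.

## The adiabatic (unified colored noise) theory

Adiabatic elimination of the noise time scale gives an approximate
stationary configurational density

    P(x) ∝ exp{ −(1/D)[Φ + (τ/2)|∇Φ|²] } · ‖I + τ∇∇Φ‖,

valid where I + τ∇∇Φ is positive definite (the package raises a validity
error otherwise, and ensemble averages count and exclude such
configurations rather than clamping them). The central object is the
velocity distribution *conditional on the positions*: a centred multivariate
Gaussian with covariance

    Cov(v | x) = (D/τ) (I + τ∇∇Φ)⁻¹.

Unlike an equilibrium Maxwell–Boltzmann fluid, velocities couple to
positions through the Hessian: variance is suppressed where curvature is
high, and velocities of nearby particles become positively correlated. All
variances are reported in units of the free value D/τ.

Closed forms implemented in `mucna`:

- single particle in an external potential: (D/τ)/(1 + τφ″(x));
- two particles at separation Δx: variance (D/2τ)(1 + 1/(1+2τφ″)) and
  cross-correlation (D/2τ)(1 − 1/(1+2τφ″)), with limits D/τ (far apart) and
  D/(2τ) (stiff contact — the centre-of-mass variance);
- position-averaged two-particle variance: quadrature of the conditional
  trace against P(Δx) on (0, L/2] (minimum-image convention; the integrand
  underflows to exactly 0 below Δx = 0.2 for every D ≤ 10⁴, so quadrature
  starts there with breakpoints bracketing the contact peak; absolute
  tolerance 10⁻¹²);
- two active hard spheres: in the hard limit P(Δx) is uniform outside
  contact plus a Dirac peak at Δx = σ whose area, obtained by substituting
  u = φ′ in ∫ e^{−τφ′²/D} 2τφ″ dΔx, is √(πDτ). Averaging D/(2τ) at contact
  against D/τ elsewhere gives

      v̄²/(D/τ) = [(1−ρσ) + ρ√(πDτ)/2] / [(1−ρσ) + ρ√(πDτ)],

  a monotone decreasing function of ρ and D, bounded below by 1/2 and
  depending on D only through ρℓ/(1−ρσ). It tracks the exact x⁻¹²
  quadrature within 0.04 absolute at D = τ = 1 over ρ ∈ [0.05, 0.8];
- mean field (uniform density, long-ranged interactions): I + τ∇∇Φ has
  (N−1) eigenvalues 1 + (N+1)τφ₂ρ/N and one eigenvalue 1 + τφ₂ρ/N, giving
  the exact finite-N trace and the large-N variance 1/(1 + τφ₂ρ). Here φ₂
  is the mean pair curvature per unit density counted on both sides of a
  particle. The force-balance closure |φ′(σ)| = √(D/τ) (propulsion rms
  speed) gives τφ₂ρ = 2ρ√(Dτ), a function of ρℓ only;
- small persistence time: φ₂ is estimated from a measured pair distribution
  function as φ₂ = ∫ g(x) · 2φ″(x)/(1 + 2τφ″(x)) dx. The kernel reduces to
  the bare curvature integral 2∫gφ″dx as τ → 0 (the literal first-order
  expansion of tr(I+τH)⁻¹/N), but the resummed denominator — the exact
  trace deficit 2τφ″/(1+2τφ″) of one isolated stiff pair — is what makes
  the formula usable for a steep core, where τφ″ is O(1–10) at the
  separations where g has weight even at τ = 0.1. The additive-deficit
  predictor 1 − ρτφ₂ (`small_tau_variance`) reproduces simulation to
  0.1–2% at τ = 0.1 across the tested (D, ρ) and to <1% at τ = 0.3,
  ρ = 0.5; the bare integral misses by 20%+;
- harmonic chain: for nearest-neighbour springs k the Hessian is the
  periodic Toeplitz matrix (diag 2k, off-diag −k) with eigenvalues
  2k(1−cos(2πm/N)); the mean inverse eigenvalue of I + τH is the Watson
  integral (1/2π)∫dθ/(1+2τk(1−cosθ)) = 1/√(1+4τk). The high-density
  mapping expands x⁻¹² to second order at the mean spacing,
  k(ρ) = 156ρ¹⁴.

## Mean-field free energy and density fluctuations

Mapping P(x) onto a Boltzmann form with effective temperature D gives, for
homogeneous ρ,

    f(ρ)/D = ρ ln ρ − ρ − ρ ln(1 − ρσ) − ρ ln(1 + τφ₂ρ),

ideal gas + Tonks hard-rod excess + the velocity-entropy term (the
mean-field log-determinant; its coefficient 1 follows directly from the
effective Hamiltonian Φ + τ|∇Φ|²/2 − D ln‖I+τ∇∇Φ‖). The velocity term acts
as a weak attraction, but as ℓ → ∞ it at most cancels the ideal-gas term,
so f″(ρ) > 0 on the whole domain — the scan over ρσ ∈ (0.01, 0.99),
D ∈ [10⁻², 10³], τ ∈ [10⁻², 10²] finds no spinodal cell. Long-wavelength
density fluctuations follow the compressibility form S(q→0) = D/(ρ f″(ρ)),
normalized so the ideal gas gives exactly 1 (the same convention as the
simulation estimator, making the two directly comparable). At high ℓ the
amplitude develops an interior maximum in ρ that grows with τ — enhanced
fluctuations and clustering without phase separation.

σ inside f defaults to 1.0 (the measured effective diameter moves by ≲15%
over a 16× range of D and can be passed explicitly).

## Simulation

Euler–Maruyama for the positions with the exact exponential OU update for
the noise (unbiased in dt for the η process). Defaults: dt = 10⁻⁴ for x⁻¹²
at the studied densities (validated on the harmonic external potential,
where the colored-noise theory is exact, to <1%); samples τ/2 apart;
equilibration 10τ; positions initialized on a jittered lattice, η drawn
from its stationary distribution. A stiffness monitor aborts when a
per-step displacement exceeds half the mean spacing, and the 1-d ring
order (conserved by the diverging core) is verified after equilibration.

Hot loops are numba kernels; Gaussian variates are drawn in fixed-size
blocks from `numpy.random.Generator(PCG64(seed))` outside the kernels, so
a trajectory is bit-reproducible from its config + seed. The recorded
velocity is always the integrator's own −∇Φ(x) + η at the sampled
positions, never a finite difference.

Problem sizes used by the test suite and the acceptance script (chosen as
desk-scale versions of the studied state points): two-particle runs of
6×10³ decorrelated samples; N = 100 runs of 5×10³–2×10⁴ samples for g(x)
and the effective diameter; one N = 1000 run of 10³ configurations for the
configuration-to-configuration spread; a 4-density × 2-τ scan at N = 64,
D = 8 for the fluctuation phenomenology.

## What the synthetic runs do and do not show

The generator *is* the model under study (there is no external data), so
simulation/theory agreement tests probe the quality of the adiabatic
approximation, not data realism. Where the theory is exact — free
particles, harmonic potentials (external or chain), the τ → 0 limit — the
pipeline reproduces it to statistical precision, which pins the integrator.
Where it is approximate, the package measures the error rather than hiding
it:

- overall velocity variance: theory averaged over simulated coordinates
  tracks the simulated variance within ~5% (τ = 0.3) to ~10% (τ = D = 1)
  at ρ = 0.5, degrading at large D;
- the stationary separation density of two particles at τ = 1 carries a
  systematic ~12% mean (30% worst-bin) error: the theory over-weights
  contact;
- conditional velocity statistics: contact (D/2τ) and far-field (D/τ)
  limits are clean, but bins one-to-two diameters out show a deficit of
  ≈0.15–0.18·D/τ — a pair leaving a collision keeps a suppressed,
  correlated velocity over the persistence length, memory the adiabatic
  elimination discards. At ≥5×10³ decorrelated samples this is
  statistically resolvable (|z| up to ~4), so the per-bin 3-standard-error
  agreement check fails in those bins by design of the physics, not by
  defect; the limit checks in the same test pass.

## Numerical choices

- Cutoff r_c = 4.0 for x⁻¹² (unshifted truncation; |φ′(r_c)| ≈ 2×10⁻⁷,
  negligible against √(D/τ)).
- Minimum-image convention everywhere, including the theory-side pair
  quadrature (consistent with the simulator at high density where
  L/2 < r_c).
- g(x) normalized so an ideal gas gives exactly 1 (per-pair expected count
  2w/L per bin of width w); the counting identity 2ρ∫g dx = N then holds.
- Conditional statistics binned by |Δx| (parity symmetry doubles
  statistics); default bin widths 0.02σ for g, 0.05σ for conditional
  stats; standard errors from 16 contiguous time blocks to respect sample
  autocorrelation.
- Density-fluctuation estimator (⟨|ρ_q|²⟩ − |⟨ρ_q⟩|²)/N at the allowed
  mode q = 2πm/L nearest to (20σ)⁻¹, m ≥ 1; the naive stderr understates
  the error of this slowly-relaxing mode (relaxation ~1/(Dq²)) and is
  labelled accordingly.
- Jackknife (delete-one over configurations) for the ensemble-averaged
  theory variance.

## Known limitations

Only d = 1 is implemented (the code validates the dimension explicitly);
attractive potentials and non-pairwise forces are out of scope; the
mean-field free energy addresses homogeneous states only (no gradient
terms, no interfacial physics); the Euler position update is first order,
so observables sensitive to the deep core (the contact edge of g) carry an
O(dt·φ″) bias, kept small by the default dt.
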