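# Methods

## Model

Two adherent cells on a linearly elastic substrate sense each other through
the deformation fields their contractile machinery imposes on the gel. Each
cell is idealized as a contractile force dipole; one cell (B) is stationary at
the centre of the domain, the other (A) is motile. In scaled units — lengths
in cell diameters σ, time in diffusion times σ²/D₀, energies in k_BT — cell A
obeys the overdamped Langevin equation

    dr/dt = −dW/dr + √(2 D_T) η(t),

with unit mobility and η unit white noise. The pair potential is piecewise:

    W(r) = ½ k_steric (1 − r)²   for 0 ≤ r ≤ 1   (soft steric core)
    W(r) = −α / r³               for r > 1        (elastic attraction)

The attractive branch is the orientation-averaged far-field interaction of two
in-plane force dipoles on an elastic half-space, which decays as 1/r³. The
three dimensionless groups are

* α = P² φ(ν) / (E k_BT σ³) — elastic coupling; inversely proportional to the
  substrate Young's modulus E, so soft substrates mean strong coupling.
  Characterized range 0.1–100.
* D_T = D_eff / D₀ — scaled motility (noise temperature of the cell's random
  exploration relative to thermal). Range 0.1–10.
* k_steric = k σ² / k_BT — steric stiffness. Range 10³–10⁴.

φ(ν) is an elastic-medium constant of order one whose exact form depends on
conventions for the dipole tensor; since all simulations are parameterized by
α directly, the package treats it as an explicit scalar (default 1.0) that
rescales α only.

### Potential branches and the effective potential

As conventionally written, the two branches do not join at r = 1: the steric
branch vanishes there while the attractive branch equals −α, and the force
jumps from 0 to 3α. `potential()` returns the branches exactly as written
(with r = 1 assigned to the steric side). The dynamics, however, only ever
consume the force, and the line integral of the branch-wise force is
continuous. `effective_potential()` returns that continuous antiderivative
(steric branch shifted by −α); it is the potential in whose Boltzmann weight
the simulated dynamics actually equilibrate, and it is what the equilibrium
oracle integrates. Using the discontinuous form in the oracle would
mis-predict the steady-state capture probability by ~0.08 at α/D_T = 5,
because the (shifted) steric core carries weight e^{α/D_T} · √(πD_T/k_steric)
that the printed branches would drop.

## Integration

Explicit half-order Euler–Maruyama:

    r(t+δt) = r(t) − ∇W|_{r(t)} δt + √(2 D_T δt) w,

with w a pair of independent standard normal draws per step. Default
δt = 10⁻³ (the protocol this package reproduces reports both 10⁻³ and 10⁻⁴
for its production runs). All trend-level observables (contact counts, exponents, plateau onset,
first-contact times) are converged at δt = 10⁻³ and stable under halving,
which the test suite checks.

Two numerical regimes require a finer step, both documented here as the
package's accuracy requirements:

* **Equilibrium-grade occupancies.** With k_steric δt = 1 the discrete chain
  inside the stiff core behaves as a discretized Ornstein–Uhlenbeck process
  whose stationary variance is inflated by the factor 2/(2 − k_steric δt);
  at δt = 10⁻³ this over-populates the core and biases P_ss by a few
  hundredths at intermediate α/D_T. Quantitative comparisons against the
  Boltzmann oracle therefore use δt = 2.5×10⁻⁴ (k_steric δt = 0.25).
* **Dipolar runs.** The anisotropic angular factor reaches g ≈ 11.4 for
  pole-to-pole alignment at ν = 0.3, so at α = 40 the effective attraction at
  contact (~3αg) exceeds 10³. Those runs use k_steric = 10⁴ (the stiff end of
  the characterized range) and δt = 5×10⁻⁵ so that the explicit spring stays
  well inside its stability region (k_steric δt = 0.5); at looser settings
  the core is penetrated deeply and the marginally-stable spring catapults
  the cell away from the pole it should adhere to.

Boundaries: *reflecting* (specular mirroring per component, repeated until in
range — the zero-flux choice) in a 12σ box with B at the centre, used for
contact and capture statistics; *periodic* (wrap modulo L, unwrapped
coordinates accumulate raw displacements) with B's images on a square lattice
of spacing 12σ, used for dispersion; *none* for free-diffusion controls. The
image-lattice force sums shells of images around the nearest site
(default 2 shells, i.e. 5×5 sites); the 1/r⁴ decay bounds the neglected tail
by ~3α/(12s−6)⁴ per omitted shell, negligible at 12σ spacing.

Reproducibility: `SeedSequence(seed)` spawns one substream per trajectory
(child 0 reserved for initial-position sampling), so runs are bit-identical
for a given seed and individual ensemble members can be replayed in
isolation. Exact cell-centre coincidence (probability zero) is handled by
redrawing that step's noise.

## Observables

* **Contacts** — an entry is a recorded sample crossing from r > 1.5σ to
  r ≤ 1.5σ (nearest image under periodic boundaries). A trajectory that
  starts inside the disc scores no entry until it leaves and returns. No
  hysteresis is applied; counts are therefore mildly sensitive to the
  sampling stride near the threshold, which the δt-stability tests bound.
* **MSD** — ensemble- and time-averaged over all reference times on the
  recorded grid (overlapping windows), computed per trajectory with the
  FFT-based O(S log S) decomposition, on unwrapped coordinates. The
  anomalous exponent is the least-squares log–log slope over a stated
  window: τ ∈ [0.1, 10] for the diffusive regime, the final decade of τ for
  late-time saturation (the reference protocol describes the regimes without
  giving fit windows).
* **Capture probability** — p_inside(t) is the ensemble fraction inside the
  contact disc; P_ss is its mean over the final quarter of the run. Its
  standard error is taken across trajectories (each trajectory's
  final-window occupancy is one independent sample), which correctly absorbs
  temporal correlation. The plateau onset tests for *resolvable* departure:
  the curve is averaged into 40 time bins and a bin counts as off-plateau
  only when it falls outside P_ss by more than max(5% of P_ss, 3 binned
  ensemble SEs). At N ≈ 300 the raw pointwise Bernoulli noise (sd ≈ 0.03)
  exceeds a literal 5% band, so a noise floor is required for the onset to
  measure drift rather than noise.
* **Radius of influence** — ℓ_M = (α/(μ_T D_T))^{1/3} with μ_T = 1 in scaled
  units: the distance at which elastic attraction balances motility.

## Equilibrium oracle

With unit mobility the reflecting-box steady state is thermal equilibrium at
effective temperature D_T, so

    P_ss = ∫_{r≤1.5} e^{−W_eff/D_T} dA / ∫_{box} e^{−W_eff/D_T} dA,

evaluated by midpoint quadrature on a uniform grid (64 cells/σ, doubled until
successive estimates differ by < 10⁻³), with the global minimum of W_eff/D_T
subtracted before exponentiating to avoid overflow. Because W_eff/D_T depends
on (α, D_T, k_steric) only through their ratios to D_T, P_ss collapses onto a
master curve in α/D_T — exactly so when k_steric is scaled with D_T. At
fixed k_steric = 10³ the collapse is approximate: the steric core carries
Boltzmann mass ≈ 2π e^{α/D_T} √(π D_T/(2 k_steric)), so pairs sharing α/D_T
but not D_T differ in P_ss by ~0.015 at α/D_T = 2 — below the resolution of
a plotted master curve but resolvable by a 150-trajectory ensemble, which is
why the collapse test holds k_steric/D_T fixed. The
test suite cross-checks the 2D midpoint rule against an independent 1D radial
quadrature (adaptive `scipy.integrate.quad` against the square's arc-length
measure), and the simulated occupancy against the oracle on a 4-point
(α, D_T) grid at 3 Monte-Carlo standard errors.

## Anisotropic (dipolar) extension

Polarized cells contract along a stress-fiber axis; the interaction then
depends on the two dipole-axis angles θ₁, θ₂ measured from the separation
vector:

    W(r, θ₁, θ₂) = −(α/r³) g(θ₁, θ₂, ν).

The default g was derived from the far-field interaction of two in-plane
contractile force dipoles on the surface of a linear elastic half-space:
surface response G_ij ∝ (1/r)[(1−ν)δ_ij + ν n_i n_j] (Boussinesq–Cerruti),
interaction energy U = −f_A·G·f_B, point-dipole limit. Carrying out the
contraction symbolically gives

    h = (1−ν)/4 + (3/4)(1−ν)(cos2θ₁ + cos2θ₂)
        + ((2−ν)/8) cos2(θ₁−θ₂) + (15ν/8) cos2(θ₁+θ₂),

whose uniform angular average is (1−ν)/4 > 0; g is h normalized by that
average, so the orientation average of W reduces *exactly* to the isotropic
−α/r³. End-to-end aligned dipoles attract (g(0,0) ≈ 11.4 at ν = 0.3),
side-by-side parallel ones repel (g(π/2, π/2) ≈ −1.6) — the angular structure
that steers a motile dipole around the repulsive equator of a stationary one
and onto its poles. The factor is pluggable (any π-periodic vectorized
`g(θ₁, θ₂, ν)` with matching gradients), so an alternative convention can be
swapped in without touching the dynamics; all qualitative behaviour exercised
by the tests (1/r³ scaling, mixed sign, pole attraction, isotropic reduction)
is convention-independent.

The force acquires a tangential component because the relative angles rotate
with the separation vector: with ψ the polar angle of r and lab-frame axis
angles φ₁, φ₂, F = −∇W = (3αg/r⁴) r̂(−) + (α/r⁴)(∂g/∂θ₁ + ∂g/∂θ₂) ψ̂ (signs
as implemented and finite-difference-checked). The dipole angle relaxes
deterministically, dθ/dt = μ_rot × torque with torque = −∂W/∂θ₁; there is no
rotational noise and no self-propulsion. μ_rot defaults to 10 (scaled), making
orientational relaxation fast relative to translation over a cell diameter —
the rapid-reorientation regime that also justifies the isotropic average in
the main model. Pinned-lattice equilibria are closed-form (the θ₁ dependence
is a single second harmonic, so the minimizer is ½·atan2(N, M)); a dense
angular scan backs this in the tests.

## Synthetic fixtures

Deterministic trajectories (stationary, ballistic, scripted radial crossings)
share the simulator's trajectory schema so every observable is unit-testable
against closed forms without stochastic runs. They emulate only the geometry
of motion — not cell-shape changes, measurement noise, frame-rate effects, or
any feature of real tracking data — so passing fixture tests validates the
observable algebra, and the stochastic tests validate the dynamics.

## Problem sizes

Defaults mirror the study conditions: reflecting box 12σ, contact radius
1.5σ, N = 1000/100 trajectories (contacts/MSD) and T = 1000 at δt = 10⁻⁴ in
the original protocol. The shipped test and acceptance runs use the same
geometry with N = 50–500, T = 50–350 and δt as above — sizes at which every
trend they assert is resolved with margin; the criterion-level tolerances
(5% on the free-diffusion constant, ±0.1 on exponents, 3 SE on equilibrium
agreement) are stated per test.

## Known limitations

* The mean first-contact time at α = 20, D_T = 2 from uniform initialization
  measures ≈ 5.4 (reflecting) / 5.7 (periodic) in scaled time, with median
  ≈ 3.5, while the reported reference value of ≈ 2 derives from the delay time at which
  the MSD slope drops. The simulated MSD reproduces precisely that slope
  minimum at τ ≈ 2–3, so the discrepancy is one of estimator (ensemble-mean
  first-passage time vs. MSD kink), not of dynamics.
* Observables near the contact threshold inherit O(√δt) sampling sensitivity
  from raw (hysteresis-free) crossing detection.
* Strain-dependent contractility, substrate-stiffness feedback, self-
  propulsion, rotational diffusion, near-contact bond kinetics, haptotaxis,
  durotaxis gradients, fibrous-matrix power laws (1/r^a, a < 3), and
  mutually interacting multi-dipole assemblies are out of scope.
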