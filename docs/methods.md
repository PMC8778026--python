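# Methods

## Scope and model chain

`nanoagg` models the aggregation of monodisperse, charge-neutral
spherical nanoparticles in a solvent, starting from the pair free-energy
profile (PMF) and ending at analytic growth laws.  The chain is

PMF curve → piecewise analytic fit → uniform force table → Langevin
(Brownian) dynamics in a periodic box → cluster kinetics trace →
Smoluchowski-type model fits.

Everything operates in a consistent nm / ps / kJ·mol⁻¹ / u unit system
(1 u·nm²·ps⁻² = 1 kJ/mol, k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹), with SI
inputs (viscosity Pa·s, Hamaker constant J) converted at the API
boundary.

## PMF representation and fitting

A PMF is sampled on a strictly increasing grid of center-to-center
distances.  Before fitting, curves are down-shifted so the mean of the
last 10% of points is zero (null interaction at infinite separation).

The fit model is two 5th-order polynomials — repulsive branch for
d ≤ d_AFE, attractive branch for d_AFE < d ≤ r_c — plus a logarithmic
tail c₁ ln d + c₀ beyond r_c.  Choices the functional form leaves open,
and how this implementation resolves them:

* **Continuity.** Value and first-derivative continuity are enforced at
  d_AFE by solving the joint linear least-squares problem in a
  null-space reduction (both branches in rescaled variables on [−1, 1]
  for conditioning, converted back to raw power-series coefficients).
  The branch junction is iterated onto the refined minimum of the
  fitted model, so the reported d_AFE is both the junction and the well
  position; continuity there is exact by construction.  At r_c the tail
  is attached with value continuity.
* **Polynomial cutoff r_c.** A single 5th-order polynomial cannot track
  a well that decays over many length scales; pushing it to the end of
  the data biases the fitted well depth by several percent.  By default
  r_c is therefore placed where the profile has decayed to 15% of the
  well depth (`tail_frac` parameter), and the remaining data fit the
  logarithmic tail (one free slope, value-continuous at r_c).  With no
  data beyond r_c the tail is attached by slope continuity instead.
* **Tail clamp.** A logarithm cannot decay to zero asymptotically, so
  the tail is used only up to its first zero crossing
  d_zero = exp(−c₀/c₁) and the potential is exactly zero beyond.  The
  tail's sign is not constrained: a curve approaching zero from below
  yields c₁ > 0, one from above c₁ < 0; both cross zero and clamp.
* **Degenerate input.** Profiles without an interior negative minimum
  (flat or monotonic) raise an error rather than returning a zero-depth
  fit.

The aggregation free energy (AFE) is the depth of the fitted minimum
relative to the zero baseline.  Fitting synthetic curves built from the
reference anatase wells (44.18 / 54.35 / 75.56 kJ/mol for
R = 0.78 / 1.50 / 2.00 nm) returns depth and position within 1%.

## Tabulation

Tables are uniform with a default 2×10⁻³ nm step.  Force is the
analytic branch derivative except at the two grid points flanking each
junction, where a central finite difference of the tabulated energy is
used.  Below the lowest fitted distance the repulsive polynomial is
extrapolated; the table is truncated where that extrapolation stops
being repulsive or exceeds 100× the well depth, and any pair closer
than the table start is reported as an overlap error by the simulator.
The table ends just past d_zero so U and F are exactly zero at d_max.

## Brownian dynamics

Each nanoparticle is one bead of stoichiometric mass (Ti 47.867 u,
O 15.999 u).  The friction rate is the Stokes drag divided by the
particle mass, γ = 6πμR/(m·u)·10⁻¹² ps⁻¹ with u = 1.66054×10⁻²⁷ kg —
the only dimensionally consistent reading of "γ in ps⁻¹" (≈0.35 ps⁻¹
for R = 1.5 nm in water at 310 K).  Water viscosity defaults to
6.913×10⁻⁴ Pa·s (310 K) and is configurable.

The integrator applies the pair force as a full kick and then the exact
Ornstein–Uhlenbeck update,

v ← e^(−γΔt) (v + FΔt/m) + ξ √(k_B T/m · (1 − e^(−2γΔt))),   x ← x + vΔt,

which satisfies fluctuation–dissipation exactly: the stationary velocity
variance is k_B T/m at any timestep, and the long-time diffusion
coefficient is k_B T/(mγ)·(1 + O((γΔt)²)).  With the default
Δt = 0.1 ps and γ ≲ 0.5 ps⁻¹ the correction is < 0.1%.  Initial
velocities are Maxwell–Boltzmann at T; initial positions are rejected
until all minimum-image pair distances exceed 2R + min_gap
(min_gap = 0.1R by default).

Pair forces are linearly interpolated from the table and accumulated
over a Verlet-style candidate list built with a linked-cell search
(cell edge ≥ table range + skin, default skin 1 nm, rebuilt every 100
steps; with the defaults the maximum two-particle drift between
rebuilds is far below the skin).  The cell grid is coarsened when the
box is much larger than the cutoff so the scan cost stays proportional
to N.  Hydrodynamic interactions between beads are neglected in the
dynamics; they enter only through B(h) in the kinetic theory below.
Runs are bit-reproducible given the state's seed.

## Cluster detection

Two particles belong to the same aggregate when their center-to-center
minimum-image distance is strictly less than 3R ("less than"; a pair at
exactly 3R is not bonded).  Displacements use
x_i − x_j − h·round((x_i−x_j)/h) with round-half-away-from-zero, so the
measure-zero tie at half a box length maps +h/2 to −h/2 (documented and
tested).  Components are found with a periodic k-d tree for candidate
pairs (re-checked against the strict threshold) and sparse connected
components; aggregates straddling the periodic boundary are single
clusters by construction.  The mean aggregate size is number-averaged
(total particles / number of clusters), matching the growth laws below.

## Aggregation kinetics

For a diffusion-limited suspension the mean particles per aggregate
follows N(t) = 1 + t/t_p with t_p = πμR³W/(k_B T φ).  The stability
ratio

W = 2R ∫₀^∞ B(h) (h+2R)⁻² exp[(W_R+W_A)/k_B T] dh,
B(h) = (6(h/R)² + 13(h/R) + 2)/(6(h/R)² + 4(h/R)),

uses W_R = 0 (charge-neutral particles) and the sphere–sphere Hamaker
attraction W_A (A_H = 6×10⁻²⁰ J for titania across water).  The
improper integral is evaluated after the substitution y = 2R/(h+2R),
which maps (0, ∞) to (0, 1] with unit Jacobian against the (h+2R)⁻²
kernel: W = ∫₀¹ B exp(W_A/k_B T) dy.  The zero-potential, B ≡ 1 case is
then exactly 1 (the acceptance tolerance on this closed form is 10⁻⁹,
which a truncated log-grid scheme cannot reach), the B(h) ~ R/2h
contact divergence is suppressed by the vanishing Boltzmann factor
(handled in log space), and the far tail needs no cutoff.  Adaptive
quadrature diagnostics (error estimate, evaluation count) are returned.

Because the linear law ignores aggregate mobility loss, a discretized
size-aware model is provided: N_i = N_{i−1} + Δt/t_p*, with
t_p* = exp(n₂ N_{i−1} φ^{1/3}) · πμR³(n₃W)/(k_B T φ), iterated from
N₀ = 1 (default Δt = t_p/1000; the iteration warns if a single step
grows N by more than 1).  n₂ = 0, n₃ = 1 recovers the linear law
exactly.  Fitting:

* `fit_n1` — one-coefficient rescaling t_p* = n₁t_p; linear in 1/n₁,
  solved in closed form.
* `fit_n2_n3` — bounded least squares on [0, 1]² from a deterministic
  5×5 grid of starts with trust-region refinement (RNG-free, so fits
  are bit-reproducible); the loss is on the number-averaged mean size
  with uniform weights.  Frames with ≤ 5 aggregates in the box are
  discarded first (late frames carry no statistics); n₃ is bounded away
  from zero (10⁻⁶) because t_p* → 0 is singular.

Noiseless round trips recover every reference (n₂, n₃) pair to 10⁻³;
with 5% multiplicative noise the mean over 50 replicates recovers both
coefficients within 3 standard errors.

## Synthetic data

The synthetic PMF generator emulates only what the downstream pipeline
consumes: a single well of prescribed depth at a prescribed distance
above contact, a steep steric wall, and a decaying tail.  It is the
sum of a scaled sphere–sphere Hamaker attraction and an exponential
wall A·exp(−h/λ) with λ = gap/3, solved as a 2×2 linear system so the
minimum is exactly −depth at h = gap.  Two regularizations make this
construction feasible at realistic well depths: the attraction is
evaluated at the smoothed separation (h³ + (gap/2)³)^{1/3} — real wells
are an order of magnitude deeper than the bare Hamaker value there, and
the scaled 1/h divergence would otherwise punch through any finite
wall — and the sampled grid starts where the wall reaches the well
depth (`wall_cap`), mimicking the limited wall height umbrella windows
sample.  The default cutoff extends until the tail is below 0.5% of the
depth.  The generator does not emulate solvent-layering oscillations or
sampling noise of real PMFs, so passing tests demonstrate correctness
of the fitting/simulation machinery, not robustness to atomistic
artifacts.

Packing: N = round(φh³/(4πR³/3)) particles for volume fraction φ;
uniform rejection sampling with per-offender resampling under a
periodic k-d tree.

## Problem sizes used in the test suite

Production studies of this kind run tens of thousands of beads for
≥ 30 µs; the suite exercises the same code paths at desk scale, chosen
as the smallest sizes whose statistics are decisive:
thermostat checks on 300 free beads over 1.2×10⁵ steps (velocity
variance to 2%, diffusion slope to 5%), a two-bead bound pair over
2×10⁶ steps for the configurational Boltzmann test (χ², p > 0.01), and
an end-to-end aggregation study of 200 beads (R = 2 nm, φ = 0.5%,
2×10⁶ × 0.1 ps) in which the smoothed mean aggregate size must grow
monotonically and the fitted n₁ is positive.  At these sizes mean
aggregate sizes reach only ≈ 2, so kinetic-coefficient values from the
scaled-down run are not comparable with production-scale fits — the
recovery of the reference coefficients is instead validated by
model-generated traces at the production timescale (30 µs).

## Known limitations

* Monodisperse, neutral spheres only; no double-layer repulsion, no
  polydispersity, no aggregate-shape descriptors.
* The BD beads feel no inter-particle hydrodynamics; B(h) exists only
  inside the stability-ratio integral.
* The log tail of the pair model is clamped to zero at its first zero
  crossing; the small kink there is below the fit residual.
* `fit_n1`/`fit_n2_n3` assume traces on a common deterministic clock;
  irregular sampling is handled by interpolation in `rmse` only.
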