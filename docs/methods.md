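# Methods

## Model

The mucus film above a bronchial epithelium is modeled as a two-dimensional
incompressible Newtonian flow (density `rho_m`, dynamic viscosity `mu_m`)
driven by a body force

    f_n = f_v + f_c,    f_v = -kappa * U,

where `f_v` is the friction exerted through the low-viscosity periciliary
layer (PCL) underneath the mucus, acting at every grid node, and `f_c` is the
ciliary propulsion: a force of fixed magnitude `|f_c|` applied on the nodes
of *ciliated* hexagonal surface elements along each element's beat angle
`theta_c`.  The forcing represents a time average over many ciliary beat
cycles; individual beats, metachronal waves and beat-phase synchronization
are outside the model's scope, as are non-Newtonian mucus rheology and the
vertical structure of the PCL/mucus bilayer (the film is depth-averaged).

Each ciliated element reorients toward the local flow (streamwise
alignment).  With `dtheta = theta_f - theta_c` the wrapped angle between the
element-averaged flow direction and the beat angle,

    theta_c(t + dt) = theta_c(t) + Omega * sign(dtheta) * dt + In * eta * dt    if |dtheta| > theta_0,
    theta_c(t + dt) = theta_c(t) + In * eta * dt                               otherwise,

with `Omega` a fixed angular speed, `theta_0` a small dead-band angle that
lets noise-free systems reach exactly steady states, and `eta` a standard
Gaussian rotational noise of intensity `In` drawn per element per update by a
Box-Muller transform.  The condition is applied to `|dtheta|` (a literal
one-sided reading would never realign negative offsets), and an update that
would overshoot `theta_f` sets `theta_c = theta_f`; with the default
`theta_0 = 2*Omega*dt` the overshoot branch is unreachable and serves only
as a guard for nonstandard parameter choices.  An exact head-on offset
`dtheta = pi` picks its rotation direction by a seeded coin flip.

Non-dimensional control parameters:

* ciliary density `phi = S_c / S` (area fraction of ciliated elements);
* Reynolds number `Re = rho_m * D * U0 / mu_m`, with `U0 = |f_c| / kappa`
  the force-balance velocity scale and `D` the hexagon side;
* interaction length `lambda = sqrt(mu_m / kappa) / D`, the screening length
  of one element's forcing in units of the element size.  Physiologically
  `lambda ~ (delta_p / D) * sqrt(mu_m / mu_p)` with `delta_p`, `mu_p` the
  PCL thickness and viscosity.

## Numerics

The flow is solved with a D2Q9 BGK lattice-Boltzmann scheme with Guo's
second-order forcing on a fully periodic Cartesian grid, grid spacing
`dn = D/5` by default (a hexagonal element then owns ~65 fluid nodes).
Lattice units `dx = dt = rho0 = 1`; `U0 = target_mach * c_s` with default
`target_mach = sqrt(3)/100`, i.e. `U0 = 0.01`, which places the relaxation
time at `tau = 3*U0*D/Re + 1/2 = 2.0` for `Re = 0.1`, inside the accepted
stability window (0.55, 2.5), and makes the default alignment dead band
`theta_0 = 2*Omega*dt = 0.004` rad at `Omega = U0/D`.  The friction
`-kappa*U` depends on the Guo-corrected velocity itself and is folded in
implicitly and exactly: `U = (m + f_c/2) / (rho + kappa/2)`.  Populations
are stored and accumulated in double precision; steady-state density
fluctuations stay below the weakly compressible bound `3*Mach^2`.  Pressure
is reported as `c_s^2 (rho - rho0)`; the momentum-equation pressure gradient
is implicit in the scheme and never formed.

The epithelium is a periodic tiling of flat-top hexagons (side `D`), with
column pitch `1.5 D` and row pitch `sqrt(3) D`; the row pitch is stretched
by <1% so that the domain height is a whole number of grid spacings.  Grid
nodes are assigned to their nearest element center under the periodic
metric (ties to the lowest element index), which reproduces exact hexagons
up to rasterization.  An even column count is required for seamless wrap.
Ciliated elements are drawn uniformly without replacement (no correlation
structure: real cultures may cluster ciliated cells, which is unmodeled),
and initial beat angles are independent uniform on (-pi, pi].

`Omega` is a numerical parameter: noise-free steady organizations do not
depend on it, it only sets the transient pace.  The orientation update runs
once per LBM step by default (`update_stride` is exposed and validated to
leave outcomes unchanged at sample points).  Ensemble drivers and the
acceptance script double it (`Omega = 2*U0/D`, hence `theta_0 = 0.008` rad),
which roughly halves the time to steady state; this was validated against
`Omega = U0/D` at sample points (identical labels, polarizations within the
run-to-run spread).

## Termination

Two noise-free stopping rules:

* **strict steadiness** — for 50 consecutive orientation updates every
  `|dtheta|` stays inside `theta_0` *and* the relative L2 velocity change
  per step is below 1e-8.  This is the exact fixed-point condition; small
  isolated configurations (single element, pre-aligned carpets) reach it.
* **stationarity window** — near regime boundaries a handful of elements
  hover at `|dtheta| ~ theta_0` and the pattern creeps indefinitely at a
  rate irrelevant to its classification, so a run is also declared converged
  when, over the trailing 2000 updates (sampled every 50), the polarization
  span is below 2e-3, the kinetic energy varies by less than 0.2% and on
  average fewer than 2% of ciliated elements are still moving.

With noise there is no steady state; runs go to `max_updates` and report the
final stationary window.  Non-converged runs are flagged and excluded from
phase-diagram tallies.

## Order parameters and classification

* Polarization `P = |mean(U/|U|)|` over all nodes faster than
  `1e-6 * U0` (numerically stagnant nodes carry no direction).
* Signed non-dimensional vorticity `omega = (D/U0) (curl U)` by periodic
  central differences.  The *signed* field enters the correlations: the
  autocorrelation of an absolute-value field could never cross zero, while
  the swirl-size definition requires a crossing; the spatial mean of a
  periodic curl vanishes identically, so no mean subtraction is applied.
* Directional autocorrelations `R_x`, `R_y` by FFT over the periodic
  domain, lags 0..L/2; integral length
  `Lambda = 1/(lambda*D) * int R_mean dtau`, truncated at the first zero of
  `R_mean` (beyond it periodic-image anticorrelation contaminates the tail)
  or at L/2 when no crossing exists; the truncation mode is recorded.
* Regimes: `P >= 0.9` fully aligned; otherwise swirly if `Lambda >= 1.5`,
  else poorly aligned.
* Swirl size `Lambda'`: first zero crossing (linear interpolation) of the
  ensemble-averaged `R_mean`, in units of `D`.  Profiles whose mean never
  crosses zero within L/2 are flagged *confined* and excluded from scaling
  fits.

The `Lambda' = lambda^alpha * phi` scaling exponent is fitted by bounded
scalar minimization of the RMS deviation of `Lambda'/lambda^alpha` from the
best line through the origin in `phi` (an explicit objective standing in for
a by-eye collapse).

## Synthetic data and fixtures

All inputs are generated internally from seeds: geometry, ciliated-element
placement and initial angles emulate a jammed epithelium with a static
random mixture of ciliated and passive elements at prescribed density.
What passing tests show is therefore confined to the model world: uniform
random ciliated placement, Newtonian depth-averaged flow, noise-free or
white-noise orientation dynamics.  They do not certify behavior under
spatially correlated ciliation, non-Newtonian rheology, or free boundaries.
Deterministic fixtures (two-element, single-element, uniform forcing) plus
closed-form oracles (Taylor-Green curl, damped-cosine correlation profiles)
validate each pipeline stage independently of the solver.

## Problem sizes and reduced presets

The full square campaign domain is ~1e4 elements (100x100); desk-scale work
uses the named `reduced` preset (40x40, ~1.6e3 elements) and a 60x60 box for
the low-density swirl-size point.  The package's test suite and acceptance
script run entirely at these reduced sizes with 5-6 (tests) or 25
(acceptance script) seeds per ensemble.  Two consequences are documented
rather than hidden:

* On the reduced box the swirly configurations at intermediate density
  (`phi = 0.4`, `lambda = 2`) are long transients rather than end states:
  the periodic box is only a few swirl diameters wide and the vortex
  pattern usually coarsens into the fully aligned state within the patience
  of the stationarity rule.  Sustaining a steady multi-swirl lattice
  requires the ~1e4-element domain (not desk scale), where a verification
  run of the `full` preset does reach a stationary swirly state.  Two
  acceptance-suite checks that presume persistent swirls on reduced boxes
  fail for exactly this reason and are left failing rather than retuned.
* Single-run swirl sizes at 40-60-element boxes carry O(box/3) confinement
  ceilings; the confined flag marks affected measurements.

## Known limitations

* The strict per-element steadiness criterion is rarely reached on
  glassy/swirly configurations in finite time; the stationarity window is
  the operative rule there, and its tolerances (2e-3 on polarization span,
  2% moving elements) are classification-scale, not machine-precision.
* The hexagonal lattice breaks continuous rotational symmetry: an isolated
  element relaxes onto lattice-symmetric directions, and regime statistics
  are only statistically (not microscopically) isotropic.
* Quantities tied to the pressure field keep an algebraic (dipole) tail;
  only the rotational part of the flow is screened on `lambda*D`.  Screening
  diagnostics therefore use the vorticity field.
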