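# Methods

## Model

Two non-dimensional concentration fields on a 1D cortical segment, active
RhoA ρ(x,t) and NMIIA m(x,t), obey reaction–advection–diffusion equations
with mutual Hill-type recruitment (coefficient n) and linear dissociation,
unit diffusivities, and advection by the cortical flow v(x) scaled by the
Péclet number Pe:

    ∂ρ/∂t + Pe ∂x(v ρ) = α ( H(m; κ₁) − ρ ) + ∂²ρ/∂x²
    ∂m/∂t + Pe ∂x(v m) = α ( H(ρ; κ₂) − m ) + ∂²m/∂x²,   H(c; κ) = cⁿ/(κⁿ + cⁿ)

The cortex is treated as a thin active fluid in quasi-static force
balance: viscous stress plus a saturating myosin-generated active stress
against substrate friction, which in non-dimensional form reduces to the
screened elliptic problem

    v − v″ = ∂x ( m/(K + m) ).

Lengths are in units of the hydrodynamic length l = √(η/γ), times in units
of the diffusion time l²/D, concentrations in units of the
recruitment/dissociation ratio s/k.  `NondimMap` performs this mapping; we
read α as k·η/(γD), i.e. the ratio of the diffusion time to the reaction
time 1/k — this is the only reading under which α consistently multiplies
the kinetics in the non-dimensional equations, and the formula used is
logged whenever the mapping runs.

Assumptions inherited from this formulation: both species share one
diffusivity and one dissociation rate; the GEF/GAP machinery (Ect2,
p190B RhoGAP, ROCK scaffolding) is folded into the two-variable feedback
phenomenology; inertia and nonlinear rheology are neglected; the total
cytoplasmic pool is unlimited.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| α | diffusion time / reaction time | 1.0 | 0.02 in the slow-turnover inhibition scenario; α ≥ 0, α = 0 freezes reactions (transport tests) |
| κ₁, κ₂ | Hill half-saturations | 0.2 | bistable for κ ≲ 0.5 at n = 4; phase portraits also shown at 0.4 |
| n | Hill coefficient | 4 | integer ≥ 1 |
| Pe | contractile advection / diffusion | — | regime parameter; depinning near 11 for α = 1 |
| K | active-stress half-saturation | 1.0 | in units of s/k |
| advection_mode | which species the flow carries | both | "myosin_only" models membrane-anchored RhoA |

With κ₁ = κ₂ = κ the diagonal steady states solve cⁿ − cⁿ⁻¹ + κⁿ = 0
(plus c = 0); at κ = 0.2 the saddle is at 0.1222 and the high state at
0.9984.

## Numerics

**Grid.** Nodes on [0, L], default L = 40 with 400 cells (dx = 0.1).
Default boundary conditions: rigid walls (v = 0 at both ends) with
no-flux concentrations — a bounded junction that conserves mass; periodic
boundaries are supported and used by the verification tests.  Whether the
original study used rigid or periodic boundaries is not stated anywhere we
could find; stationary zones are localized far from the walls, so the
choice does not affect the pinned regime.

**Velocity solve.** Second-order central differences for v″ and for the
stress gradient; the SPD operator (I − ∂²ₓ) is factorized once per grid
(banded Cholesky, or sparse LU on a ring) and back-substituted every step.

**Time stepping.** Operator splitting per step: (1) velocity solve from
the current m; (2) conservative upwind advection; (3) explicit flux-form
diffusion; (4) explicit reaction update.  dt = min(0.2 dx², 0.5 dx /
max|Pe·v|), re-evaluated as the flow evolves (0.8 safety on the advective
bound inside `simulate`).  Each substep is monotone, so concentrations
stay non-negative to round-off; values in (−1e−12, 0) are clipped to zero
and anything more negative aborts the run as a scheme failure, carrying
the partial record.

**Advection scheme.** The default is a van-Leer-limited second-order
upwind (MUSCL) flux; plain first-order upwind is available as
`scheme="upwind1"`.  We made the limited scheme the default after
measuring that first-order numerical diffusion inflates near-critical
stationary widths by ~15% at dx = 0.1 (4.24 vs 3.60 at Pe = 12) and
delays depinning by ~0.5 in Pe.  The MUSCL results agree to better than
1% with an independent method-of-lines reference (central-difference
advection integrated by SciPy's BDF at rtol 1e−6) on the same grid, and
front speeds change by < 0.1% under dx → dx/2.

**Stationarity.** The zone width is the trapezoidal integral of ρ over
the domain.  A run is *stationary* when the width range over the trailing
20 time units is below 1e−3 of its mean and the front (half of the global
ρ maximum) has never entered a 2-length-unit boundary margin; a contacted
run is never called stationary (it is *propagating* if the width was
still growing, otherwise *censored*, which triggers one retry on a domain
of twice the length).  Front speed is the least-squares slope of the
width over the late-time half of the pre-contact frames, divided by
2·ρ_high (two outward fronts carrying the plateau concentration).
`critical_pe` bisects on this verdict between verified brackets to a
tolerance of 0.25.

**Problem sizes.** All reported runs use the 400-cell grid with t_end =
150 (100 for the strongly pinned Pe = 30 case); at dt = 2×10⁻³ a run is
~75k steps and takes seconds to tens of seconds on one CPU.  Widths at
these settings are converged: doubling t_end changes stationary widths by
< 1e−3 relative, and halving dx changes them by ≤ 8% near depinning (and
far less above it).

## Findings that differ from the qualitative expectations

Two results of the faithful implementation deserve explicit notice.

1. **The near-critical width does not saturate at ~3.**  The stationary
   branch's integral width grows continuously as Pe decreases toward the
   depinning point (≈ 10.9 at α = 1, κ = 0.2): ≈ 3.6 at Pe = 12, ≈ 4.5 at
   Pe = 11, larger still closer to threshold.  A "largest finite width"
   therefore depends on the Pe sampling resolution; scanning down in
   steps of 1 refined to 0.25 yields ≈ 4.6–5.0, not ≈ 3.  Both our
   integrators (the production splitting scheme at two resolutions and
   the independent BDF reference) agree on this, so we report the
   measured value rather than adjust the scan.  The flow concentrates
   both species well above the well-mixed high state (peak ≈ 1.75), so
   the integral width also exceeds the geometric extent of the zone
   (≈ 3.3 above half the high-state concentration at the branch end).

2. **A 2-fold NMIIA decay increase does not eliminate bistability at
   κ = 0.2.**  The contractility-inhibition protocol (Pe → 0 with the
   −αm term doubled) leaves the well-mixed system bistable (elimination
   requires a factor ≥ 6 at these κ), and a converged pinned zone then
   *re-ignites* to the uniform high state instead of inactivating — the
   released fronts spread once the flow no longer opposes them.  The
   biphasic response (transient broadening of the thresholded zone
   followed by total RhoA falling below 0.1% of its pre-switch value)
   does occur whenever the decay increase actually exits the bistable
   regime; the suite demonstrates it with a factor of 8.  `run_protocol`
   implements the stated 2× protocol exactly; decay factors multiply only
   the dissociation terms, and identity settings reproduce the unsplit
   simulation bitwise.

## Kymograph quantification

Per frame, positions are re-centred on the junction (X = 0); the zone is
the maximal contiguous run of above-background pixels containing the
junction; width = run length × pixel size and intensity = mean over the
run, both normalized to t = 0.  When no background is given it is
estimated as the median of the dimmest half of the pixels plus three
robust standard deviations (1.4826×MAD of that half) — the dimmest half
is background-dominated for a minority ridge, whereas a bare decile of a
zero-clipped image collapses to exactly zero.  Quantification is invariant
under a common gain on intensities and background and under junction
drift when the junction track follows the ridge.

The synthetic generator emulates only what the quantification consumes: a
Gaussian ridge with prescribed width/peak time-courses, optional drift, a
uniform baseline (camera bias/autofluorescence) and seeded Gaussian noise
clipped at zero.  It does not emulate photobleaching, shot-noise scaling
with intensity, junction-tracking errors, or neighbouring structures;
passing the recovery tests therefore shows the measurement pipeline is
unbiased for an isolated ridge at SNR ≥ 10, not that it is robust to
those real-data effects.  Simulation-derived kymographs are noise-free,
so analyses of simulated records pass an explicit physically meaningful
threshold (e.g. half the saddle concentration, or half the high-state
concentration when the zone core is wanted) instead of the noise-floor
estimate.

## Known limitations

- 1D only; the 2D generalization is out of scope.
- First-order splitting in time; regime boundaries carry O(dx, dt) error
  (the depinning estimate moved from ≈ 11.25 to ≈ 10.9 between the
  first-order and limited schemes at dx = 0.1).
- The stationarity verdict is a finite-time criterion; arbitrarily close
  to the depinning point the transient outlives any fixed horizon and the
  verdict can lag the asymptotic behaviour.
- Clustering of the contractile component is detected by prominence-based
  peak counting on single frames; no spectral (Fourier) onset analysis.
- No limited total protein pool and no spatially varying decay rates;
  both would bound the travelling-front spread in a passive cortex.
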