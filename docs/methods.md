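# Methods

`seedwave` estimates two material property surfaces of a lentil seed —
the dielectric loss factor ε″(T′, M) and the effective moisture
diffusivity D(T, M) — from a single microwave drying record, by inverse
simulation: a coupled heat/moisture finite-element model of one seed is
run forward, and the property-model coefficients are adjusted until the
simulated mean surface temperature and mean moisture content match the
measured series.

## Forward model

**Geometry.** The seed is a biconvex lens: two identical spherical caps
joined at their circular base, overall diameter d = 4.4 mm and thickness
t = 2.2 mm by default. With cap base radius a = d/2 and cap height
h = t/2 the circumscribing sphere radius is R = (a² + h²)/(2h), giving
V = 2πh²(3R − h)/3, A = 4πRh, and a characteristic length
L = V/A = 0.48 mm for the default seed. The computational domain is the
half cross-section in the (r, z) plane, revolved about z. The
cross-section is convex, so a Delaunay triangulation of boundary plus
interior points is a valid conforming mesh; the default edge length
(90 µm) yields roughly 480 nodes and 870 linear triangles.

**Governing equations.** Energy balance (Fourier conduction, uniform
microwave volumetric source, evaporation sink) and moisture transport
(Fick's second law):

    ρ(M) Cp(T, M) ∂T/∂t = ∇·(k_eff ∇T) + q_MW − H_evap · M_v
    ∂M/∂t = ∇·(D_eff ∇M),          M_v = −ρ ∂M/∂t

with q_MW = 2πf ε₀ ε″ E². M is dry-basis moisture (kg water / kg dry
matter). The evaporation sink is applied nodewise from the moisture
increment of the same time interval. Both curved surfaces carry Robin
conditions parameterised by fixed Biot numbers,

    n·(k ∇T) = h (Ta − T),    h  = Bi_heat · k / L
    n·(−D ∇M) = h_m (M − Me), h_m = Bi_mass · D / L

with ambient Ta = 296.15 K and equilibrium moisture Me = 0 by default;
h and h_m are re-evaluated each step from the local k and D (a config
flag freezes them at the initial state instead). The symmetry axis is a
zero-flux boundary. Shrinkage, the contact patch with the tray, cavity
electromagnetics and field attenuation are all neglected: at 2.45 GHz
the penetration depth in lentil (~2 cm) far exceeds the seed thickness,
so a uniform field is assumed.

**Property correlations.** Density is quadratic in M; specific heat and
thermal conductivity depend on the wet-basis moisture fraction
w = M/(1+M); latent heat is linear and decreasing in T. Two temperature
conventions are deliberate and enforced: the specific-heat and
loss-factor polynomials take Celsius temperature T′ (a kelvin argument
puts Cp near 4000 J/kg/K for moist lentil, far outside the measured
range for pulses), while both diffusivity exponents take kelvin with
the Arrhenius factor exp(−Ea·10³/(8.3143·T)), Ea in kJ/mol. This
pairing reproduces the published diffusivity magnitudes (1e-9–1e-6
m²/s); the literal kmol-based constant printed alongside Ea in kJ/mol
does not.

**Parametric property models.**

    ε″ = g0 + g1 T′ + g2 T′² + 100 g3 M + 100 g4 M T′
         + g5 A + g6 A² + g7 A T′,      A = ash_db / (1 + M)
    D  = D0 exp(−Ea·10³/(R T)) · exp((a0 T − a1) M)

A is the wet-basis ash content; the dry-basis ash percentage is not
altered by the process and defaults to 2.6 % (typical red lentil; the
source study does not print its value, so individual g-coefficients are
only meaningful jointly with it).

**Field strength.** E is derived from the available magnetron power
Pav and reflection coefficient S11 as √(2·Pav/(1 − S11²)) in V/cm
(default), with the alternative √(2·Pav·(1 − S11²)) and a direct-E
override selectable. Any constant miscalibration of E is absorbed by
the fitted ε″ scale, so the inverse estimates are invariant to this
choice up to a rescaling of the g-coefficients. Defaults: Pav = 616 W
(0.7 kW nominal) with S11 = 0.421, or Pav = 308 W with S11 = 0.694.

**Discretisation.** Linear (P1) triangles with r-weighted mass,
stiffness and boundary matrices; backward-Euler time stepping; a
segregated coupling (one implicit moisture step, then one implicit heat
step per interval) with all property coefficients lagged to the start
of the step. Systems of a few hundred unknowns are solved with a direct
sparse factorisation. Default dt = 0.5 s for simulation (1 s inside the
estimation loop). The consistent mass matrix makes the insulated
moisture balance conserve total content exactly per step (verified to
1e-8), and energy bookkeeping (absorbed microwave energy vs enthalpy
gain) closes to ~1e-12 on insulated runs. A run is aborted (and, inside
the optimiser, penalised) when |T| exceeds 600 K or M turns negative.
Summaries are extracted by revolved-volume weighting (mean),
revolved-area weighting over the convective boundary (surface), and the
node nearest the origin (center).

## Inverse estimation

Two sum-square errors are formed against the record: SSE_T (surface
temperature, °C²) and SSE_M (mean moisture, (d.b.)²).

**Stage 1 — decoupled lumped initial guesses.** The seed is taken
spatially uniform at the measured state, smoothed by a five-harmonic
Fourier series (offset, five cosine/sine pairs and the fundamental
frequency; fitted by variable projection — the problem is linear for
fixed ω, and ω is optimised by a bounded scalar search around
2π/record length). The moisture balance dM/dt = −(Bi_m D(T(t),M)/L²)(M−Me)
is fitted for (D0, Ea, a0, a1[, Bi_mass]) and the energy balance
ρCp dT/dt = q_MW − (Bi_h k/L²)(T−Ta) − H_evap ρ dM/dt for
(g0…g7[, Bi_heat]), each by a bound-clipped Nelder–Mead simplex (in a
unit cube; D0 and Biot numbers on log scales) followed by a bounded
quasi-Newton polish that is accepted only when it improves. Starting
points come from inverting the smoothed record for the *required*
property trajectory — D_req(t) from the decay rate, ε″_req(t) from the
energy residual — and fitting the model linearly (bounds-constrained)
to it; a mid-bounds start replaces this when the inversion is
degenerate. The lumped temperature equation has positive feedback (ε″
grows with T), so its integration clamps temperature to [−50, 250] °C
with a quadratic penalty; without this the simplex wanders into
thermally explosive coefficient corners. Degenerate records (no
moisture change; no temperature range) are flagged, not fatal.

**Stage 2 — goal attainment on the coupled model.** All coefficients
(twelve property coefficients, optionally plus both Biot numbers) are
refined jointly by minimising the attainment level γ subject to

    SSE_T(C) − w_T γ ≤ goal_T
    s·SSE_M(C) − w_M γ ≤ s·goal_M
    ε″(T′, M) > 0 at every trajectory sample
    lb ≤ C ≤ ub

with unit weights. The goals are the SSE pair that the stage-1
coefficients achieve through the full coupled model, so the start is
feasible with γ = 0 and every accepted iterate improves on it. The
moisture scale s defaults to goal_T/goal_M, making the two scaled goals
coincide so that the unit weights exert symmetric relative pressure;
it is configurable. The scalarised problem (slack variable γ plus
inequality constraints, normalised so the slack is O(1) beside the
unit-cube coefficients) is solved by sequential quadratic programming
with finite-difference gradients — the forward map is smooth and
deterministic. Iterates are ranked by the *implied* attainment level
max((SSE_T−goal_T)/w_T, s(SSE_M−goal_M)/w_M), which equals the slack at
optimality; an iterate is accepted when its ε″ constraint holds and its
implied level improves, so γ is non-increasing along the accepted
sequence and the reported optimum is the best accepted point. The
search also stops when the step norm falls below twice the step-size
tolerance (1e-6) at a feasible point. An infeasible start is repaired
by shrinking toward mid-bounds and, failing that, by substituting the
bounds-constrained ε″-regression coefficients. Default bounds are the
published per-treatment coefficient ranges expanded by 50 % of the
half-range, with Bi ∈ (1e-4, 0.1).

**Identifiability.** Mean-series moisture data constrain the product
Bi_m·D(T, M)/L² — exactly so in the lumped limit and to O(Bi²) in the
FEM — so the diffusivity *scale* is recoverable only when Bi_mass is
known; temperature dynamics do separate Bi_heat from the heating scale
(rise rate vs plateau). The documented contract of a fit is therefore
the ε″ and D surfaces along the traversed trajectory, not individual
coefficients (which are additionally confounded with the assumed ash
content and any field-strength miscalibration). The parameter-recovery
tests condition on known Biot numbers; `optimize_biot=True` (default)
reproduces the full published protocol and reports the product-level
estimate.

## Synthetic data

The generator runs the forward model with known coefficient rows as
ground truth and samples the surface temperature and mean moisture on a
15 s schedule, stopping when mean moisture returns to the 0.10 d.b.
storage level (capped at 30 min). Six presets cover 2 nominal powers ×
3 tempering moistures (0.20/0.35/0.50 d.b.), with the published
per-treatment coefficients, Biot optima (0.043/0.038 heat, 0.015/0.016
mass) and per-power source calibrations; the initial temperature is
4 °C, inside the reported 3–6 °C band. Measurement noise is i.i.d.
Gaussian per channel, σ_T = 0.5 °C (infrared camera sensitivity plus
handling) and σ_M = 0.003 d.b. (0.01 g balance on ~50 g samples, with
margin) by default; the initial moisture sample is exact because the
tempering target is known. Real records differ in ways the generator
does not emulate: the ~20 s out-of-oven measurement interruptions (and
their cooling transients), possibly heteroscedastic or drifting errors,
seed-to-seed variability within the drying layer, and shrinkage.
Passing recovery tests therefore demonstrate the estimator's
correctness and conditioning on the stated error model, not robustness
to those effects.

## Test problem sizes and margins

The suite and the recovery checks run at the estimation operating
point: mesh edge 0.25 mm (~260 triangles), dt = 1 s, 6-minute records
at 15 s sampling, goal-attainment iteration caps of 20 (noise-free) and
12 (noisy); self-convergence tests cover the refinement direction
(halving dt or the edge length moves final means by < 1 %). Measured
recovery at this point: noise-free trajectory errors ~1–2 % for both
surfaces (contracts: 5 % for D, 10 % for ε″); with σ_T = 1 °C,
σ_M = 0.005 d.b. noise, worst-of-five-seeds ~7 % (contract 15 %).

## Known limitations

- The lumped stage-1 temperature model is structurally unstable for
  ε″ models that grow with T; it serves only to produce starting
  points, and its SSE can be far above the coupled model's floor.
- With `optimize_biot=True`, reported D0 (and Bi_mass) are one point on
  the Bi·D ridge; only their product is data-determined.
- The positivity constraint on ε″ is enforced at trajectory samples,
  not over the whole (T′, M) rectangle.
- No uncertainty quantification on coefficients; no multi-treatment
  joint fitting; no frequency dependence of the dielectric response.
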