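# Methods

## Model

A frying disc is treated as an infinite slab of full thickness δ; symmetry
reduces the domain to the half-slab [0, δ/2] with y measured from the
surface. Shrinkage, oil uptake and in-core water diffusion are neglected:
the core is water-saturated, the crust dry and porous, and all moisture
leaves through the evaporation front at the in-tissue boiling temperature
T_b. Heat transfer is pure conduction in each region with constant
per-region properties (k, ρ, c_p), convective exchange with the oil at the
surface, and a Stefan balance at the front: the net conducted flux equals
ρ_core·w·λ_w·dY/dt, the latent sink of the water held in the tissue being
dried. Per unit volume of swept core this latent load is ρ_core·w·λ_w —
the same quantity in the front-tracking solver, the enthalpy relation and
the closed-form estimate, which is what makes the three mutually
consistent (see "Capacity density" below).

Two boiling-temperature modes exist. `fixed` holds T_b = 103 °C, the value
observed in potato tissue (slightly above 100 °C because steam nucleates
in the superheated front region). `variable` raises T_b with the
normalized front position x = Y/(δ/2),

    T_b(x) = min(T_b0 + A·exp(B·x), cap),   A = 7e-10 °C, B = 25.455,

modeling solute concentration in the shrinking wet core. The exponential
is so sharp that the elevation is negligible until x ≈ 0.8 and tens of
degrees only near x → 1. The cap defaults to T_oil − 0.5 °C: an unclamped
curve exceeds the oil temperature at x = 1, which a convectively heated
disc cannot reach.

## Variable space network (VSN) solver

Three phases. **A** — sensible heating of the fresh disc on a uniform grid
(2J+1 nodes) with h_sensible until the surface reaches T_b. **B** — a
crust of thickness 2% of δ is seeded (a linear profile across the seed;
1–2.5% is thick enough that the seeded increment does not collapse the
time step, and thin enough to be harmless) and the domain splits into two
moving grids of J increments each. Interior nodes follow the Murray–Landis
update (grid-advection term plus diffusion); the surface node is a
finite-volume half-cell with h_boiling; the front is pinned at θ = T − T_b
= 0 and advances by the Stefan balance, with second-order one-sided
gradients built from the front value and the two nearest nodes on each
side. The time step is re-limited every step (the core increment shrinks),
and the front advance per step is capped at a fraction of the smaller
increment. **C** — when the front comes within `switch_fraction`·δ
(default 2%) of the center, the remnant core is absorbed and a single
all-crust region continues sensible heating with h_sensible until the
center reaches `stop_center_temp` (default T_oil − 1) or `t_max`.

The collapse at the B→C switch deletes the remnant core's latent sink, so
the center temperature lifts off the converged trajectory — visible as a
jump. It is an artifact of the switch, recorded as an event, and fades as
`switch_fraction` → 0.01 (verified in the suite by comparing against a
run switched at 1.05%).

With variable T_b, θ arrays are shifted by (T_b_old − T_b_new) each step
so stored physical temperatures stay continuous.

Sign conventions: the two-region updates are formulated on the half-slab,
so core denominators use (δ/2 − Y) with the symmetry plane at δ/2, and
the interface stencils are the one-sided differences described above; the
scheme is validated against the closed-form frying time and the
conduction series rather than by matching any particular typography of
the update formulas.

## Enthalpy solver

Single fixed grid of N nodes over the half-slab. Evaporation is smeared
over a narrow band T_b ± ε (ε default 0.5 °C); the specific enthalpy

    H(T) = C_co·T                                   T < T_b − ε
         = C_co(T_b−ε) + [(C_co+C_cr)/2 + wλ_w/2ε](T−T_b+ε)   in the band
         = C_cr·T + wλ_w + (C_co−C_cr)·T_b          T > T_b + ε

is continuous, strictly increasing, and exactly invertible (the solver
converts H→T each step through the piecewise-linear inverse). The update
is a conservative finite-volume step of ρ∂H/∂t = ∂(k∂T/∂y)/∂y with
harmonic-mean face conductivities (flux continuity across the ~7× k
contrast), per-node k blended linearly across the band, half control
volumes at the surface (convective flux; h_boiling while any node is in
the band, h_sensible otherwise) and center (zero flux). The fixed time
step honors both the interior diffusion bound — with margin for face
conductivities up to twice the nodal value — and the surface-node bound;
`dt_safety` defaults to 0.4.

**Capacity density.** The density multiplying ∂H/∂t while a node crosses
the band is configurable. The default `core` keeps ρ_core until the node
is fully crust, so the latent heat absorbed per unit volume is
ρ_core·w·λ_w — identical to the Stefan balance and the quasi-steady form,
and the reason all three methods agree on the frying time. The
alternative `mixture` uses the linear core/crust mixture
ρ = (1−X)ρ_core + X·ρ_crust (X the crust fraction, the linear map of the
band onto [0,1]); it under-weights the latent load by roughly the mean
density ratio (≈0.67) and shortens the plateau by about a third — kept
available, and tested, precisely to quantify that modeling choice.

**Front extraction.** The front position is read from the temperature
field, by default the interpolated depth where T crosses T_b
(`crust_fraction_half`; `first_node_above_Tb` takes the deepest node at or
above T_b). The reading is ratcheted — an evaporation front cannot
retreat — which matters in variable mode, where the raw reading is the
intersection of the temperature profile with the elevation curve and
would otherwise oscillate.

**Variable T_b.** When the band moves, wet nodes keep their enthalpy
unchanged: H is the physical state, and preserving it conserves the
latent budget (re-basing to preserve temperature would force a node to
absorb wλ_w·ΔT_b/2ε of spurious extra latent for every degree the band
rises during its crossing — implemented first, measured, and rejected
because it stalls the run unphysically). Nodes that have fully vaporized
are flagged dry and stay on the crust branch permanently, with the branch
offset (C_co−C_cr)·T_b updated so their temperature is continuous. In
variable mode the band top chases the cap, so "center exits the band" can
never fire; completion is instead declared when the ratcheted front
reaches the center — all free water gone. A late consequence of the sharp
exponential: the center temperature can step upward with the band in the
final seconds as the last water flashes off; temperatures remain bounded
by the cap.

**Energy audit.** During stepping the solver accumulates the exact
surface-flux energy. The audit compares it with Δ∫E(T)dy, where
E(T) = ∫ρ dH is the closed-form volumetric enthalpy state function
(piecewise linear/quadratic, matching the configured capacity-density
rule). The residual is the path-integration error of evaluating ρ at the
start of each step while a node crosses the band; it scales with the time
step, hence ∝ 1/N², giving a discretization check that is small (~2e-5 at
N=50) and strictly improves with refinement. The audit is defined for
fixed-T_b runs; with a moving band the state function is ill-defined and
the function warns.

## Quasi-steady frying time

t = (1/β)(δ/2h + δ²/8k_cr), β = (T_oil − T_b)/(ρ_core·λ_w·w), derived by
neglecting sensible heat (a few percent of the latent load). The
denominator's moisture factor is the moisture mass fraction w; the
published symbol for it collides with the enthalpy band half-width, so the
package names them separately (`PropertySet.w` vs `epsilon`). Two
moisture values are exposed on purpose: the measured w = 0.738 (solver
default, t ≈ 818 s) and w_eff = 0.73, which reproduces the canonical
809 s reference value; λ_w defaults to 2.2565e6 J/kg, the saturation value
at 100 °C, since no measured value exists for the tissue.

## Boiling-point-elevation fitting

`fit_boiling_elevation` maps water-loss percentage linearly to x
(100% ↔ x = 1; the front position determines the water remaining, hence
its boiling point), adds the nucleation `shift` (default +3 °C — steam
bubbles nucleate in the superheated front during frying but not in the
extracted-liquid boiling experiment the calibration data come from), and
fits ln ΔT_b = ln A + B·x by least squares **weighted by ΔT_b²**. The
weights are the inverse delta-method variances when measurement noise is
additive in °C: without them a ±0.5 °C error on a near-zero elevation
moves its log by several units and can bias the slope by tens of percent;
with them noise-free data are still recovered exactly and the slope from
noisy data is unbiased to within a few percent. Non-positive shifted
elevations are dropped with a warning; fewer than three usable points is
an error. The shift is applied only during fitting — at simulation time
T_b0 = 103 °C already embodies the nucleation superheat, and applying it
twice would double-count. Whether the original calibration anchored the
shifted curve at 0 or 3 °C at zero loss cannot be recovered from the
coefficients alone (the default curve evaluates to ~0 at x = 0 despite
the shift); both behaviors are available through `shift`.

## Moisture balances

Initial water = fresh mass − oven-dry mass; remaining % = 100 × (stop mass
− dry mass)/(initial water); removed % is its exact complement. Batch
summaries report both the mean of per-record percentages and the
percentage of mean masses — the conventions differ and both are emitted.
The overall moisture content of a tuber is the mean of its surface and
center measurements.

## Synthetic traces

The generator emulates the three dominant sources of replicate-to-replicate
variability in measured center-temperature traces: disc-to-disc moisture,
drawn uniformly from (0.69, 0.80) — the span measured across individual
tubers; thermocouple displacement from the center, zero-mean normal with
σ = 0.3 mm truncated to the half-slab (the probe itself is 0.5 mm); and
i.i.d. Gaussian sensor noise, σ = 0.5 °C. Ten replicates by default,
sampled at 1 s, all randomness through one seeded generator
(bit-reproducible). What it deliberately does not emulate: tissue
heterogeneity within a disc, pre-treatment effects on cell structure, oil
temperature excursions, or probe lag — so passing comparison tests shows
the pipeline discriminates the modeled variability sources, not that the
model captures every feature of real measurements. The moisture span
reproduces the qualitative spread pattern of measured replicates: traces
coincide through the sensible rise and early plateau and fan out after it,
because the water load sets when each disc's plateau ends.

Plateau detection (for phase-timing offsets) finds the longest interval
with |dT/dt| < 0.02 °C/s inside 95–115 °C; thresholds are arguments.
Comparison metrics interpolate the model center trace linearly onto each
measured grid, with no smoothing of measured data.

## Problem sizes and defaults

VSN: J = 8 increments per region, safety 0.45, snapshot every 1 s.
Enthalpy: N = 50 nodes, safety 0.4, ε = 0.5 °C. These resolve the
completion time to well under the few-percent level the cross-method
comparison probes (doubling J changes the center history by < 0.4 °C;
doubling N moves the completion time by ~0.3%). The conduction-limit
checks run at N = 200 (enthalpy) over the first minute of heating, where
the series solution converges quickly. The noisy-fit recovery uses 100
seeded replicates. Equilibrium and CLI tests use deliberately small
`t_max` values; the physics there is trivial.

A side effect of the convection schedule worth knowing: when the
coefficient switches (up at boiling onset, down when the last node leaves
the band) the surface supply changes discontinuously and the outer nodes
cool transiently by up to ~1 °C before the new quasi-steady profile
establishes. Nodal enthalpy is therefore monotone non-decreasing
everywhere except in short windows around those two events; this is the
prescribed boundary schedule acting, not a property of the discretization.

## Known limitations

- One-dimensional slab geometry only; the enthalpy formulation extends to
  2-D/3-D naturally but the package does not implement it.
- Constant per-region properties; no oil uptake, shrinkage, or
  gelatinization effects.
- The variable-T_b coupling reads the front from the temperature field;
  near x → 1 the profile/elevation-curve intersection saturates and the
  final flash-off is abrupt rather than smooth.
- The closed form presumes a constant driving ΔT and has no variable-T_b
  version.
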