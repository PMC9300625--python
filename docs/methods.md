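# Methods

This note records the model equations as implemented, the defaults and why
they were chosen, the numerical schemes, and the limits of what the test
suite demonstrates.

## Layer structure and time stepping

One driver step of `dt` hours (default 0.5 h) executes in fixed order:
(1) quasi-steady solves of oxygen, VEGF and glucose; (2) subcellular ODE
advance using local oxygen; (3) the cellular-automaton step; (4) the
vascular step (sprouting, tip migration, anastomosis, flow solve,
remodeling); (5) a field re-solve on the updated tissue and vasculature;
(6) per-cell metabolic integration against the frozen local glucose and
oxygen. Metabolism is integrated only after the final field update of the
step, so the diffusible and metabolic layers synchronize on the same
frozen state, and the coupling is strictly one-way: with the same seed,
disabling metabolism leaves cells, vessels and fields bitwise unchanged
(asserted in the suite).

All computations use one internal unit system — µm, h, mmol/l, Pa —
with conversion only at the configuration boundary (`angiomet.units`).

## Subcellular ODEs

Per cell, with local oxygen `ox` (mmol/l):

* cycle phase: dφ/dt = (ox/(ox+k_φ))/T_min for proliferating cells,
  capped at 1; division occurs at φ = 1 into a uniformly chosen empty
  26-neighbour (deferred under contact inhibition). T_min = 48 h (normal)
  / 24 h (cancer); k_φ = 0.02 / 0.01 mmol/l.
* p53: dp/dt = a − b·(ox/(ox+k_p))·p, a = 0.2/h, b = 2/h, k_p = 0.02
  mmol/l — degradation needs oxygen, so p53 accumulates under hypoxia.
  Apoptosis when p exceeds a threshold that depends on the occupied
  fraction of the 26-neighbourhood (low-density 0.8 / high-density 1.6
  for normal cells; effectively disabled for cancer cells, which die
  instead through prolonged quiescence).
* intracellular VEGF: dv/dt = a_v·k^n/(k^n + ox^n) − b_v·v with
  a_v = 0.4/h, b_v = 0.6/h, k = 0.02 mmol/l, Hill exponent n = 3. The
  sharp Hill switch represents the switch-like stabilization of the
  hypoxic transcriptional response; with a first-order form the small
  normoxic production, summed over a confluent tissue, swamped the
  hypoxic signal on small domains.

Both linear ODEs advance by their exact exponential update, so the
subcellular layer is unconditionally stable for any `dt` (the suite checks
dt = 0.5 h against the closed form). CDH and p27 are carried as passive,
default-disabled channels; no dynamics are defined for them.

Quiescence: normal cells enter below 0.035 mmol/l O₂, leave above 0.045,
and die after 24 h quiescent; cancer cells enter below 0.012, leave above
0.025, and survive 150 h. This asymmetry — cancer tolerates hypoxia far
longer — is what lets a hypoxic tumour displace healthy tissue under the
one-cell-per-site constraint.

## Diffusible fields

Each species solves
D ∇²c + k_v(x)(c_blood − c) − r_max·c/(K_M+c)·I(x) + s(x) − δc = 0
on the lattice. The vessel-exchange coefficient is assembled per site as
k_v = P · Σ 2πR·(L/2) / V_site over the functional segments touching the
site (each segment donates half its length to each endpoint), which is the
per-volume normalization of the line-source term; the cellular sink treats
r_max as a volumetric rate per occupied site, as its units suggest.

Defaults: glucose D = 2.0×10⁻⁶ cm²/s, c_blood = 5 mmol/l (physiological
plasma glucose), P_Glu = 2000 µm/h — a value chosen, and documented as
uncalibrated, so that a single parent vessel keeps c > K_M within ~100 µm
of its axis in consuming tissue (verified in `examples/02_glucose_field.py`).
Oxygen: D = 2.0×10⁻⁵ cm²/s, c_blood = 0.13 mmol/l (arterial dissolved O₂),
K_M = 0.01 mmol/l, consumption 5 (normal) and 240 (cancer) mmol/(l·h),
P = 2×10⁵ µm/h. Normal-tissue consumption sits at the physiological scale
and reproduces the classic 100–200 µm oxygen diffusion limit; the cancer
value is deliberately above physiological so that a ~100 µm tumour can
out-consume the vascularized supply of the small test domains — it stands
in for the much larger tumours of full-size runs. VEGF: D = 1.0×10⁻⁶
cm²/s, decay 10/h (localizing the field to ~190 µm), secretion = 1/h ×
intracellular VEGF of the occupant, and a vessel-clearance term with
c_blood = 0.

Discretization: second-order 7-point stencil, cell-centred, zero-flux
faces by default (Dirichlet on all faces or on the x-min face only as
config options). The nonlinear Michaelis sink is handled by Picard
iteration with the denominator lagged one iteration; each linear pass is a
warm-started, diagonally preconditioned conjugate-gradient solve (direct
factorization below 1024 unknowns). Convergence is declared on the true
nonlinear residual at 1e-8 relative (configurable). The lagged system is
an M-matrix, so converged solutions are non-negative without clipping, and
the discrete maximum principle (0 ≤ c ≤ c_blood without production) holds.
The suite verifies the solver against an independently assembled direct
solve (1e-6), the 1D cosh closed form (1e-3 at 128 nodes), a Richardson
convergence order ≥ 2, discrete conservation (influx = uptake at 1e-8),
idempotence, and the comparison principle (an added sink never raises the
field).

## Vasculature

Sprouting: each functional node without an active tip spawns one with
probability p_max·V/(V+V_half)·dt (p_max = 0.4/h, V_half = 0.02), gated by
an activation threshold V_min = 0.005: below it no sprouting occurs. The
threshold is this package's addition — without it the residual normoxic
VEGF background drove continuous angiogenesis in healthy tissue.

Tip migration: one lattice hop per event (rate tip_speed = 1 site/h),
direction drawn with probabilities ∝ exp(w·(V_nb − V_here)/d_nb)
(w = 2000 µm per field unit), never re-entering the immediately previous
site; the vacated site is laid down as a microvessel segment. Stalled or
over-age tips (60 h) regress.

Anastomosis: candidates are all other active tips and all
functional-vessel nodes within Δx_max = 100 µm, excluding the tip's own
trail and functional nodes within `tip_exclusion_radius` (default Δx_max)
of its attachment node — without that exclusion a newborn tip fuses back
into its parent vessel at distance ~0. Candidates are evaluated
nearest-first with a stable (kind, index) tie-break; for each, one uniform
draw ξ is compared with 1 − d/Δx_max; the first success connects the tip
to the target along a deterministic monotone (Bresenham) lattice path and
deactivates the tip (both tips, if tip–tip). One attempt per tip per
vascular step avoids step-size-dependent double counting.

Blood flow: conductances g = πR⁴/(8µL) with plasma viscosity 1.2×10⁻³
Pa·s; interior pressures from Σ g(p_i−p_j) = 0 with prescribed boundary
pressures (4000/2000 Pa), solved by successive displacement (SOR) with a
near-optimal relaxation factor estimated from the Jacobi spectral radius,
warm-started from the previous solve, to 1e-14 relative residual (with a
roundoff-floor stagnation guard). Components not connected to a boundary
node carry zero flow. A segment is functional when |Q| exceeds 1e-6 of
the net inflow. Remodeling relaxes each functional radius as
dR/dt = k_r·R·ln(τ/τ_ref), τ = 4µ|Q|/(πR³), k_r = 0.02/h, clamped to
[2, 12] µm; segments unperfused longer than 40 h are pruned. τ_ref = 15 Pa
is the parent-vessel operating point: the pure shear-set-point law is
structurally unstable under fixed boundary pressures (τ ∝ R at fixed
pressure drop), so the set point is placed at the initial equilibrium and
the rate kept slow; radii then drift only modestly over a few hundred
hours.

## Lin-log metabolism

The bundled default network is a 10-species, 10-reaction HEPG2-like
topology: glucose → g6p → f16bp → pyruvate, branching to lactate (with
export) and to acetyl-CoA → TCA → an oxygen-consuming respiration step,
plus the pentose-phosphate shunt g6p → 6-phosphogluconate → f16bp.
External species (extracellular glucose, oxygen, exported lactate) are
clamped. Its parameters are synthetic but internally consistent: fluxes
balance exactly at the reference state (N·J⁰ = 0 on internal species,
validated to 1e-10 on load), the reference identity r(c⁰) = J⁰ holds
exactly, and the reference Jacobian is Hurwitz. The file format
(YAML: species{name, c0, external}, reactions{J0, stoich, elasticities by
role}) accepts a full published parameterization verbatim; elasticities
are stored inputs, never recomputed, and enter the rate with exactly their
stored signs. Enzyme levels c_E/c_E⁰ are fixed at 1. Lin-log rates can go
negative at extreme logarithms; they are not clipped (the known pathology
of the functional form is preserved), and the near-zero clamp on external
concentrations is floored at 10⁻¹² of reference so log arguments stay
finite in the anaerobic limit.

Integration is performed in log-concentration space (positivity is then
structural): the public single-cell integrator uses scipy's BDF with
analytic Jacobian (a stiff, error-controlled substitute for extrapolation
codes such as LIMEX, validated against the matrix-exponential
linearization oracle at 1e-4); the driver advances all cells at once with
a batched backward-Euler scheme using per-cell adaptive step sizes,
step-doubling error control and local extrapolation (effective order 2),
with Newton systems solved by numpy's batched linear solver. Driver-level
tolerances default to rtol 1e-5 / atol 1e-8; the batched path agrees with
BDF to ~1e-6 at rtol 1e-7 in the suite.

## Default scenario

`initialize_scenario` lays two straight countercurrent parent vessels on
opposite sides of the domain (prescribed pressures reversed between
them), seeds healthy cells at the configured density, runs a burn-in
(clock from −burn_in to 0, metabolism idle) during which the healthy
tissue both proliferates and — where hypoxic — recruits vessels, then
implants a spherical tumour at the domain centre at t = 0 (radius in
sites, Euclidean; phases uniform in [0,1)) and sets every cell's
metabolic state to the reference. Everything is driven by one seeded
NumPy generator; identical seeds give bitwise-identical trajectories, and
snapshots (HDF5 state + CSV tables + JSON manifest with the RNG state)
restore and resume bitwise (both asserted).

With the default parameters this scenario reproduces, on a scaled domain,
the qualitative sequence of vascular tumour growth: burn-in angiogenesis
sustains the healthy tissue; the implanted tumour grows, out-consumes its
supply and develops a hypoxic, quiescent region; hypoxic cells secrete
VEGF; sprouts migrate and complete perfused loops; and intracellular
lactate mirrors the glucose supply (aerobic glycolysis).

## Problem sizes used by the tests

The automated checks run the growth scenario at 20³ sites for 100
simulated hours on one seed (plus 16³ scenarios for the coupling
contracts), and compare the distance-dependent anastomosis rule against
contact-only fusion on a fixed two-parent-vessel, static-VEGF-hotspot
scenario with a fixed tip cohort over 20 seeds. These sizes are the
package's default verification scale; the simulator itself runs the full
64³ / 350 h configuration unchanged, just longer.

## Known limitations

* One cell per site: no mechanics, adhesion or multi-occupancy crowding;
  tumour expansion requires adjacent cell death.
* Vessels are not displaced or co-opted by the tumour; vessel oxygen
  content is prescribed, with no intravascular depletion, haematocrit
  partitioning or advected solutes.
* The shear-set-point remodeling law has no downstream pressure feedback;
  stability is imposed by the choice of set point and bounds.
* The synthetic-data scenarios emulate geometry, stochasticity and the
  coupling structure of vascularized tissue, not any measured tumour:
  passing tests demonstrate correctness of the numerics and the stated
  qualitative phenomenology, not quantitative agreement with experiments.
* The bundled metabolic parameterization is synthetic-but-consistent;
  quantitative metabolite predictions require supplying a fitted network
  file.
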