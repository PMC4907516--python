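# Methods

`retsim` is a mechanistic, quasi-static simulator of progressive capillary
occlusion in the diabetic retina.  It couples four physical layers on a
single vascular network: Poiseuille network hemodynamics, oxygen transport
(conveyor-belt advection in vessels, pairwise contact-area diffusion and
Michaelis–Menten consumption in tissue), a VEGF reaction–diffusion field
sourced by hypoxic Mueller cells, and a stochastic, VEGF-promoted /
flow-protected occlusion process with threshold-VEGF edema.  The central
hypothesis it operationalizes is an adverse feedback loop: a capillary
occlusion makes a patch of tissue hypoxic; hypoxic Mueller cells synthesize
VEGF; local VEGF raises the occlusion hazard of neighbouring capillaries
(a proxy for ICAM-mediated leukostasis); their loss deepens the hypoxia.

## Model objects

The tissue is a 2.5-D scaffold: square tiles of pitch `a_mc` (default
12 μm, the nominal Mueller-cell size) in the XY plane carrying a thickness
(50 μm) in Z, alternately labelled Mueller cell (MC) and other retinal
tissue (OT) on a checkerboard.  Capillary blocks (CAP) are laid along each
segment centreline at 10 μm per block and exchange with the tile containing
their midpoint.  The avascular zone, when present, collapses to a single
pinned cell (oxygen source at `po2_faz_mmHg`, VEGF sink at 0).  Edema fluid
portions are a per-column volume accumulator rather than motile cells: the
only observable they support is the thickness map, which is all the model
uses them for.

Diffusive exchange between cells i and j is `J = D·A_ij·(C_i − C_j)` with
`A_ij` the shared contact area.  Tissue–tissue contacts are shared tile
edges × thickness; capillary–tissue contacts are the block's lateral
surface scaled by an interface factor (1.5 for capillaries; 2.0 for trunk
arterioles/venules, whose wide oxygenated halos act as barriers to
occlusion propagation; the leaky/edema response is disabled for trunks for
the same thick-wall reason).

## Hemodynamics

Node pressures solve mass conservation with segment conductance
`g = π d⁴ / (128 μ L)` (blood viscosity 2 cP) and Dirichlet boundary
pressures (arterial 38 mmHg, venous 18 mmHg; intermediate boundaries
interpolated by length-weighted graph distance).  The solve runs on the
patent subgraph; occluded segments (diameter pinned to ε_d = 10⁻⁶ μm)
carry exactly zero flow, and patent islands created by occlusions get a
zero-flow solution rather than an ill-conditioned global system.  The
Kirchhoff residual is verified below 10⁻⁹ of total inflow.

After every occlusion event each patent capillary adapts its diameter by
`1 + clip(k_adapt·ln(τ/τ_ref))`, where τ is wall shear stress and τ_ref its
construction-time value; the dilation step is capped at +1 % per event and
the constriction step at 15 % of that (the acute shear response is
dilation-dominant — a symmetric law nets zero and cannot produce the
hyperemic inflow rise seen early in progressive runs), with hard bounds
[0.8, 1.3]× the reference diameter.  Trunks are exempt.

## Oxygen transport

Each perfused segment is discretized into a chain of uniform conveyor
belts.  The ideal belt size is `v·Δt_f` (flux step Δt_f = 0.002 s), floored
at 0.5 μm for slow segments; the belt count is the largest number of
uniform belts of at least that size tiling the segment.  A chain whose
belt size equals `v·Δt_f` hands each belt's whole volume to the next belt
per step — the literal conveyor action; slower chains move the Courant
fraction of each belt per step, which conveys at exactly the blood
velocity on average and leaves the steady state genuinely stationary
(discrete sub-cadence shifts produce a permanent ripple that defeats any
convergence criterion).  At junctions, discharged last-belt volumes split
among downstream chains in proportion to volumetric flow; inlet chains
refill with arterial-tension blood (42 mmHg; secondary inlets at 80 % of
that).  Belts map to the capillary block containing their centre; before
diffusion each block sums its belts, and after diffusion the belts are
rescaled by the block's post/pre-diffusion ratio, so advection and
diffusion compose without double counting.  A block whose pre-diffusion
volume is zero distributes any diffused-in oxygen over its belts by blood
volume (the alternative — leaving the belts empty — silently deletes that
oxygen at the next advection and breaks global conservation).

Blood carries oxygen at 30× the tissue capacity per mmHg (a lumped
hemoglobin-binding factor; without it tissue demand outstrips convective
supply several-fold at physiological flows).  Consumption is
Michaelis–Menten (`vmax` 1.0 mmHg/s, `Km` 4 mmHg) in MC and OT cells only.
The steady-state driver iterates advect → belts-to-blocks →
diffuse+consume → blocks-to-belts; convergence is judged on 200-iteration
block means (per-iteration-equivalent relative change below `tol_ss`
= 10⁻⁶ for two consecutive blocks), which resolves steady states to the
~1 % level.  A compiled (numba) kernel mirrors the numpy reference path
operation for operation; the numpy path remains as fallback and as the
implementation exercised by the unit tests.

The oxygen constants were set by the deterministic calibration procedure
on the 65-μm hexagonal reference lattice: no cell below the 4 mmHg
hypoxia threshold at the pre-occlusion steady state, the bulk of cells
(55 %) in the 10–25 mmHg band with a unimodal histogram, and near-vessel
cells (the capillary blocks and their host tiles) reaching the mid-30s
mmHg.  These three targets cannot coexist with a steep tissue gradient on
a 65-μm lattice; the calibrated regime is interface-limited — most of the
drop occurs at the vessel wall, and the tissue forms a broad plateau whose
level is set by the supply/consumption balance.  The same lattice sits
deliberately at the critical spacing: one deleted edge leaves tension just
above threshold, two adjacent losses push the enclosed patch below it.

## VEGF

Hypoxic MCs (tension strictly below 4 mmHg; reversible state) produce
VEGF at `k_syn·(1 − C/4)·(1 − V/V_sat)` (linear ramps; a concave oxygen
ramp lets marginally hypoxic wavefront cells produce enough VEGF to drive
an unbounded occlusion wave and was rejected).  All MCs additionally carry
the small basal synthesis that balances whole-tissue first-order decay at
the basal level `v_b = 1` A.U. (volume-weighted, since MCs are the only
producers but every cell decays).  VEGF diffuses on the same contact graph
(`D_V` = 15 μm/s) and decays at `k_dec` = 0.1 /s, giving an effective
range of ≈ 40 μm — a few cell widths, enough to reach the capillaries
bordering an ischemic patch and little more.  The avascular-zone cell is a
pinned sink.  The steady state is computed directly: the stationarity
condition is linear except for the saturation ramp, so the driver solves
the sparse linear system with the saturation folded into the matrix and
iterates on the active set; this reaches the same fixed point as explicit
stepping without its `1/(k_dec·Δt)` iteration count.

## Occlusion, leakiness, edema

Every 28 model days each patent non-trunk segment draws a Bernoulli trial
with `p = p_max · V^h/(V^h + V_half^h) · exp(−v/v_scale)` using the
segment-mean VEGF over its blocks and its blood speed (p_max = 0.9,
V_half = 2.8 A.U., h = 10, v_scale = 6000 μm/s).  The steep Hill separates
the segments bathed by an ischemic patch (V ≈ 3–5) from distant or
rail-shielded segments (V ≈ 1–1.7) and keeps the basal hazard (V = 1)
negligible; the velocity factor protects fast vessels, so slow
juxtafoveal and distal-ladder capillaries fail first.  Occlusion is
irreversible, acts on the whole segment, and triggers a diameter
adaptation pass and recomputation of all steady states.  Draws run in
ascending segment id from the replicate's own stream, making every
trajectory bit-reproducible from (network, config, seed).

Weekly (every 7 model days), a capillary whose block-maximum VEGF exceeds
`mvegf_thr_leak` = 4 A.U. turns leaky (reversible); each leaky segment
deposits one fluid portion (3000 μm³) into the tissue column under its
midpoint, and every wet column drains up to 1500 μm³ (the pigment
epithelium pump), so net thickening requires sustained leakage and wet
regions dry out after their vessels occlude.

## Event loop and ensembles

Steady states are treated as instantaneous relative to the weekly/monthly
disease clocks (the flux physics equilibrates in model seconds).  A run:
assign boundary conditions → flow → oxygen → VEGF steady states →
first occlusion (a user-designated segment in `forced` mode — defaulting
to the patent capillary nearest the avascular rim, the clinically typical
first lesion — or the first spontaneous success in `spontaneous` mode;
the clock is week 0 at that event) → weekly leaky/edema checks and
four-weekly occlusion checks for 156 weeks, recomputing all steady states
(warm-started) after any occlusion, terminating early if no patent
arterial-venous path remains.  Checkpoints every 4 weeks and at events
record inflow, mean MC oxygen, hypoxic MC fraction, mean d_min/a_MC,
4-mmHg oxygen histograms, patent count and thickness change.

Ensembles rerun one network over independent seeds; summaries include
per-segment patency frequency, flow–oxygen phase points, and the
progressive classification (final inflow or mean MC oxygen below 75 % of
baseline).  The locality analysis compares the mean line-graph distance
from the forced site to all secondary occlusions against a uniform-random
null by permutation.  The phase-trajectory orientation is the shoelace
signed area in normalized (inflow, oxygen) coordinates; clockwise
(negative) passage corresponds to the progressive route through high-flow
/ low-oxygen before collapse of both.

## Synthetic networks: what they emulate and what they do not

* **Hexagonal lattice** (65 μm edges, optional random edge deletion):
  the abstract spacing-criticality testbed and the calibration reference.
* **Peripheral ladder**: 3 arteriovenous sectors, rails tapering 20→12 μm,
  18-μm apical shunts, 10-μm rungs every 140 μm across 360-μm sectors.
  Chosen so a single mid-rung loss opens an ischemic gap (ignition) while
  the rail halos confine propagation to the initiating sector.
* **Macular sector**: 510×600 μm footprint; arteriolar/venular trunks hug
  the sector rim and curl around a 150×380 μm avascular half-ellipse;
  a perifoveal arcade (ring capillary) runs along the rim between the
  trunk tips, fed only from its ends, so the loss of any ring link
  stagnates the rim band — the FAZ-enlargement ignition observed
  clinically; the interior is a Delaunay mesh pruned to the relative
  neighbourhood graph (degree ≈ 3, 52–64 μm spacing) with capillary
  diameters ~ N(5, 0.5) μm.

None of the generators reproduces a specific patient's digitized
vasculature; passing ensemble tests therefore demonstrates the mechanism
(focal ignition, VEGF-mediated local propagation, barrier effects,
hyperemia-then-collapse hemodynamics) on archetypal geometries, not a
patient-level trajectory.  Network variability enters only through the
generator seed; replicate ensembles on a fixed network isolate the
stochasticity of the occlusion draws, mirroring the patency-map design.

## Numerical choices and degenerate inputs

Explicit diffusion stability (`Δt·D·ΣA/capacity < 1`) is checked at
configuration; tile grids round the last row/column into [0.5, 1.5]×pitch
to avoid sliver cells.  Segments slower than 2 μm/s are treated as
non-advecting (their blocks exchange by diffusion only).  Zero patent
segments yield a defined zero-flow solution and infinite cell-to-vessel
distances.  An occlusion of an already-occluded segment warns and is a
no-op.  Steady states are deterministic for fixed inputs; warm-started
recomputation after events keeps a 156-week macular run near 10 s and a
ladder run near 30–60 s on one CPU, which is what makes 20–30-replicate
ensembles practical in the test suite.

## Known limitations

* Single-lamina vasculature; no multi-layer plexus, no choroidal supply
  to photoreceptors (excluded from the tissue by construction).
* Edema is threshold-VEGF bookkeeping only — no Starling mechanics, no
  cyst geometry; fluid portions do not participate in diffusion.
* The occlusion hazard's functional form (Hill in VEGF × exponential in
  speed) and all kinetic constants are calibrated, not measured; the
  spontaneous (non-focal) occlusion rate is deliberately kept near zero
  so that focal propagation and sector confinement dominate — the
  spontaneous run mode exists but rarely fires within its wait cap.
* Oxygen content is linear in tension (constant capacity factor); no
  explicit hemoglobin dissociation curve.
* The hexagonal histogram targets are met in an interface-limited
  transport regime; the 35–40 mmHg near-vessel class is carried by the
  capillary blocks and their host tiles rather than by a broad
  perivascular tissue shell.
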