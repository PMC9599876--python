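# Methods

`rosnerve` simulates the production, diffusion and scavenging of a single
reactive-oxygen species — superoxide (O2−) or hydrogen peroxide (H2O2) — in
a voxelized model of optic-nerve tissue, together with a cellular-automaton
model of oxidative axonal degeneration.  This note records the model, the
defaults and their rationale, the numerical choices, and what the shipped
desk-scale experiments do and do not demonstrate.

## Tissue model

The nerve is a disc of parallel axons.  Axons are non-overlapping circles in
the coronal (XY) plane, placed by largest-first dart-throwing rejection
sampling.  Diameters follow per-octant truncated lognormal laws; the shipped
default skews small fibres temporally (median diameter 0.65 µm in octant T
rising to 0.95 µm in N, σ_log = 0.35, truncated to [0.5, 2.5] µm) and sets
per-octant densities ∝ 1/E[d²], normalized so a full nerve (radius 750 µm)
holds 1.2 million axons at roughly equal area fill (~41 %) per octant.  An
"x %" reduced model is a disc of radius x/100 of the full nerve with the
same diameter laws, so its axon count scales as (x/100)².

On the grid (default 7 px/µm coronal, 1 px/µm axial; a voxel is a cuboid of
(1/res_xy)²·(1/res_z) µm³), each axon's rasterized disc is split into an
interior and a one-voxel boundary layer that represents the membrane.  The
membrane is one voxel thick at every resolution: its permeability is the
physical quantity, mapped to a voxel diffusion coefficient by D_m = P_m·L
with L the voxel edge, so refining the grid thins the membrane while
conserving flux.  Axons too small to have a distinct interior at the chosen
resolution are rejected at build time.

Along Z the model is zoned into unmyelinated, internodal, paranodal and
node-of-Ranvier slabs.  Myelinated-slab membrane voxels carry the myelin
permeability (20× attenuated: 0.2 µm of myelin over 10 nm membranes is 10
folds, i.e. 20 membranes in series); node slabs carry the bare membrane
permeability.  Paranodal means "myelinated and within `paranodal_extent_um`
(default 2 µm) of a node", where mitochondria cluster in real axons.

Mitochondria occupy single voxels, drawn per voxel by independent Bernoulli
trials at `mito_axon_pct`/100 in axon interiors and `mito_glia_pct`/100 in
the extra-axonal space (glia are represented by their mitochondria only).
Node slabs never receive mitochondria.  At the default axial resolution of
1 px/µm a mitochondrion voxel is ~1 µm long, matching the size used for the
single-volume mitochondrion abstraction.

## Reaction–diffusion model

One species per run obeys dc/dt = ∇·(D∇c) + RP − RS·c with per-voxel
coefficients:

* D: free diffusion `d_free_um2_s` (default 2000 µm²/s, the aqueous value,
  shared by both species) in interiors and extra-axonal space; membrane
  voxels get (D_m, D_m, 0) — axially blocking — with D_m from the zone's
  permeability.  H2O2 default P_m = 20 µm/s (literature range ~2–200 for
  cell membranes); superoxide P_m = 0 (charged, membrane-impermeant: the
  measured 2.1×10⁻² µm/s maps to D_m = 2.1×10⁻³ µm²/s at 10 px/µm,
  indistinguishable from zero in practice).
* RP (accepted in µM/s, stored in nM/s): nonzero only at mitochondrion
  voxels.  Two hypotheses: RP_SAME (every mitochondrion produces `rp_h`)
  and RP_FCONST (rate = α·f/(R·mito%), inversely proportional to axon
  radius at constant firing frequency — conduction cost scales with
  membrane area ~R, mitochondrial volume with R²·mito%).
* RS (1/s): `rs_intra` in interiors, `rs_extra` outside, both defaulting to
  10 /s — a sub-second intracellular H2O2 lifetime, consistent with the
  high peroxidase activity of neural tissue.  Membrane-class voxels do not
  scavenge (a membrane's only medium property is its diffusion).
  Mitochondrion voxels scavenge at `rs_mito_factor` (default 5) times the
  local rate, representing matrix antioxidant systems (SOD2, peroxiredoxin,
  glutathione).  This term is what makes mean H2O2 *fall* with rising
  mito% under RP_FCONST (total production is mito%-invariant there, so the
  trend must come from scavenging that grows with mitochondrial volume)
  while RP_SAME means still rise; both trends are asserted in the tests.
  Per-zone multipliers (`zone_rs`) implement scenarios such as internodal
  scavenging reduced to 70 %.

### Axial production zoning

Unmyelinated mitochondria produce at the full rate.  In myelinated axons
conduction is saltatory, so demand concentrates at the node: paranodal
mitochondria jointly share a fixed budget equal to `paranodal_fraction`
(default 0.75, the conduction share of neuronal energy) of the production
an unmyelinated stretch of the node's length would host — the budget is
split across however many paranodal mitochondria the Bernoulli draw
produced, so per-mitochondrion rates fall when more are present.  Distant
internodal mitochondria run at `internodal_fraction` (default 0.05) of the
nodal rate, covering homeostatic demand.  Node voxels produce nothing.

## Numerics

Explicit forward-Euler/central-difference (FTCS) integration in flux form.
The face flux between voxels uses the harmonic mean of their axis diffusion
coefficients, so a zero-diffusion membrane blocks exactly and the
permeability interpretation survives discretization: the measured
trans-membrane conductance matches a two-compartment ODE with effective
permeability P_eff = P_m/(1 + P_m·dx/D_free) — a sub-percent correction at
the default parameters — with box volumes excluding the (quasi-steady)
membrane voxel.  Domain boundaries are no-flux; with production and
scavenging off, total amount is conserved to rounding (asserted at 10⁻¹⁰
over 10³ steps).

The time step is the standard stability bound
dt = 0.9 / (4·maxD_xy·res_xy² + 2·maxD_z·res_z² + maxRS), which guarantees
non-negative updates (face coefficients never exceed the voxel maxima).
A NaN or negative concentration aborts the run with a diagnostic.

Steady states are detected when the maximum absolute change per second,
relative to the field maximum, drops below `tol` (default 10⁻⁴ /s).  For
frozen-state (pre-degeneration) questions the package also solves the
steady linear system (RS − ∇·D∇)c = RP directly by Jacobi-preconditioned
conjugate gradients; completely isolated, unscavenged voxels (e.g.
membranes of an impermeable species) keep their initial value.  The direct
solve is cross-checked against time stepping in the test suite and is what
the calibration routine uses.

Concentrations are stored in nM as float64; c₀ (default 0) initializes every
voxel uniformly.

## Degeneration model

State units are axonal segments (z-slabs of one axon; a single-slice model
has one segment per axon) and individual glial mitochondria.  A unit's
representative concentration is the mean over its interior voxels
(configurable to the max over its mitochondrion voxels).  States: Healthy,
Stressed, Dead.

* H→S at `stress_threshold_nM` (default 100 nM, the oxidative-distress
  boundary); S→H below it (recovery allowed by default; the dwell clock
  resets), matching the bidirectional H↔S arrows of the state scheme.
* any→D at `death_threshold_nM` (default 1000 nM);
* S→D when the accumulated dwell in S reaches `stress_dwell_s`.  No
  measured value exists for this timer; the default is 60 s (biological)
  and the desk-scale experiments compress it to 0.5 s so cascades complete
  within a few simulated seconds.
* D is absorbing; production by a dead unit's mitochondria is exactly 0.

In the Stress state production is multiplied by a factor limited to ±30 %:
0.7 under NF_RP (production falls), 1.0 or 1.3 under PF_RP.  Glial
mitochondria follow the same machine with their own (configurable) mode.

The loop alternates `cadence` solver steps (default 10) with one state
update.  When the field is steady and no transitions occurred but stressed
units still accumulate dwell time, the loop jumps to the next timer expiry
instead of integrating the wait — exact, because a steady field holds unit
concentrations constant — which is what makes the 60 s default tractable; a
test asserts the jump reproduces the explicitly integrated result.

## Calibration

The absolute production/scavenging magnitudes behind the published
phenomenology are not public, so the package ships a calibration routine
instead of guessed constants: given a target mean steady concentration over
a chosen domain (axon interiors by default), one frozen-state steady solve
fixes the production magnitude exactly (the system is linear in it).  The
degeneration scenarios calibrate the mean *intra-axonal* H2O2 to 80 nM —
just under the 100 nM distress threshold — so that only axons in the upper
tail of the per-axon production distribution (those whose Bernoulli draw
gave them several mitochondria, weighted by 1/R under RP_FCONST) sustain
stress.  This operating point is what produces partial, tail-driven loss:
survival then rises with mito% because the per-axon production distribution
concentrates (its tail thins) while mitochondrial scavenging grows.

## Desk-scale experiments

`rosnerve.experiments` reproduces the study designs at sizes one CPU
handles in seconds to minutes; radii are small but each model keeps the
full diameter laws and resolution (7 px/µm):

| scenario | model | size |
|---|---|---|
| superoxide independence | single-slice disc, P_m = 0, RP_SAME | r = 15 µm, ~480 axons |
| octant contrast / mito trends | single-slice disc, frozen states | r = 10 µm, ~210 axons |
| region contrast | abridged longitudinal 50/200/5/155 µm, dz = 5 µm | r = 4.5 µm |
| injury locus, NF sweep | single-slice disc + 10 µm node slice | r = 6 µm, ~75 axons |
| PF neighborhood loss | single-slice disc, mito% 8, P_m = 200 µm/s, RS = 50 /s | r = 10 µm, ~210 axons |

Two of the PF scenario's settings deserve explanation.  It uses the high
end of the membrane-permeability literature (200 µm/s): at high P_m every
axon's interior tracks the local extra-axonal pool, so fate is decided by
*where* an axon sits rather than by its own mitochondrial draw — the
essence of neighborhood loss, which grows with permeability.  And its
scavenging rate is raised to 50 /s so that the pool's interaction length
√(D/RS) ≈ 6 µm is smaller than the 10 µm disc: in a full-size nerve
(radius 750 µm) even the default RS = 10 /s gives an interaction length
(~14 µm) that is tiny relative to the nerve, so patches form naturally;
a desk-scale disc must shrink the length along with the model or the pool
is spatially flat and no clustering can exist.  Its calibration target
(125 nM mean intra-axonal) places the pool at the distress threshold so
loss is pool-mediated and partial — a fully dead model would make the
clustering statistic degenerate.

What these runs demonstrate: the qualitative contrasts — axon-autonomous
interspersed loss without membrane transport versus clustered neighborhood
loss with it; temporal-first gradients under RP_FCONST; opposite mito%
trends under the two production hypotheses; unmyelinated-over-internodal
zonal gradients; sparing of myelinated segments under NF_RP; survival
rising with mitochondrial content.  What they do not demonstrate:
quantitative loss magnitudes at full nerve scale, real diameter histograms
(the per-octant lognormals are parametric stand-ins; the source histograms
are not published), axial mitochondrial transport, glial cell geometry, or
timescales of the human disease (the compressed dwell timer and small
domains make biological time in these runs illustrative only).

## Analysis conventions

Coronal octants are half-open 45° wedges centred on the compass directions
of a right nerve viewed from the front: temporal left, nasal right,
superior up, inferior down; a boundary angle belongs to the
counter-clockwise wedge.  Octant loss is max(10·log₁₀(alive/total), −101)
dB — the floor stands in for −∞ at complete loss and is below the value a
single survivor could produce in any realistic octant; an empty octant has
no defined loss and is reported as not applicable rather than −101.

The neighborhood-loss statistic is this package's own quantification of
spatially clustered loss (the phenomenon has no published quantitative
definition): the mean fraction of each dead axon's k = 6 nearest
neighbours that are also dead, compared with a 999-permutation null that
shuffles the dead labels over axon positions.  Random labellings calibrate
to z ≈ N(0, 1); contiguous dead patches give z ≫ 3.

Plane slices follow the display convention: coronal shows XY (temporal
left, superior top), transverse shows XZ (proximal top), sagittal shows ZY
(proximal left, superior top).  Heatmap exports always write their
vmin/vmax (nM) to a sidecar rather than autoscaling silently.

## Known limitations

Axons are straight and parallel; glia have no cell boundaries; only one
species is active per run (the dismutation source feeding H2O2 is folded
into RP); membranes are single voxels, so sub-voxel membrane structure is
out of reach; the explicit scheme's step shrinks quadratically with
resolution, which is why the desk-scale experiments stay at 7 px/µm; and
the stress dwell timer and absolute production magnitudes are calibrated
quantities, not measurements.
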