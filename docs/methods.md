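# Methods

`lymphflow` couples five physical layers on a shared explicit time step: a
weakly compressible D2Q9 lattice-Boltzmann fluid, an overdamped viscoelastic
vessel wall, passive bi-leaflet valves, a deformable immersed cell membrane,
and a Ca++/NO reaction-transport layer that drives autonomous contractions.
This note records the model equations as implemented, the unit mapping, the
numerical choices and their rationale, and what the desk-scale study
conditions do and do not represent.

## Fluid

The fluid is BGK D2Q9 with Guo second-order forcing; the macroscopic
velocity carries the half-force shift `u = (Σ f_i e_i + F/2)/ρ`.  Gravity
enters as a uniform axial body-force density on all fluid-carrying nodes
(lumen, permeable gaps, porous tissue), switched on over a 0.05 s ramp —
an impulsive start launches an unphysical rarefaction jet at the blind
upstream end of the vessel.

Boundaries:

- **no-slip / moving walls** — halfway bounce-back with the standard
  `2 w_i ρ (e_i·u_w)/c_s²` moving-wall correction; the momentum impulse
  delivered to the fluid is returned so action–reaction is exact by
  construction;
- **porous tissue** — Walsh partial bounce-back: a fraction `ns` of every
  post-collision population is swapped with its opposite before streaming
  (`ns = 0.8` for interstitium, `ns = 1` handled as plain solid);
- **pressure outlet** — Zou–He non-equilibrium bounce-back on the east
  lumen boundary at `ρ_out = p_out/c_s²`;
- **tissue far field** — domain-edge nodes clamped to the equilibrium
  distribution at the far-field tissue density with zero velocity
  (quiescent-tissue assumption), which lets the interior draw fluid in or
  push it out according to the interior pressure.

**Primary-valve leak rule.** Gap nodes in the initial-lymphatic wall are
open when the transwall density gradient favours inflow.  When it favours
backflow the node applies a symmetric partial reflection with `ns = 0.85`:
any population leaving toward the tissue keeps exactly 15% of its mass and
85% returns to the opposite direction.  The symmetric form matters: a
one-sided "diode" that reflects only outgoing populations while admitting
all incoming ones pumps mass even at equal pressures (each population is
O(w_i ρ), not a net flux) and is violently unstable.  The symmetric rule is
neutral at equilibrium and mass-conserving to machine precision.

## Unit mapping and the gravity scale

The mapping is fixed by the lattice spacing `dx = D₀/resolution`
(baseline lumen diameter `D₀ = 0.02 cm`), the relaxation time `τ`, and the
physical kinematic viscosity `ν = 10⁻² cm²/s`, giving
`dt = c_s²(τ−½)dx²/ν`.  At the default coarse resolution (10 nodes across
the lumen, `τ = 1`) this yields `dx = 20 µm`, `dt = 66.7 µs`, and a lattice
sound speed of ≈17 cm/s.

A literal 1 g axial body force over the 5.6 mm vessel implies a hydrostatic
head of ≈550 dyn/cm², i.e. a density span of ~1.9 lattice units — far
outside the weakly compressible regime the lattice sound speed can carry.
The chain presets therefore apply a reduced gravitational scale
(`gravity_scale = 0.025`, so "1 g" maps to 24.5 cm/s² along the axis).
This keeps the head at a few percent of ρc_s² while preserving the regime
structure the model is about: adverse gravity pressurises and distends the
vessel, throttles flow, and lets Ca++ build to threshold; assisting gravity
drives fast forward flow whose wall shear sustains NO and silences the
pacemaker.  Resolving literal gravity would need `dt ≲ 5 µs` (hundreds of
thousands of steps per simulated second), which is outside the intended
desk scale of these presets; the mapping itself (`RunConfig.g_lattice_x`)
is exact and `gravity_scale = 1` restores it.

## Vessel wall

Each wall chain node (one per lattice column, top and bottom) is tethered
to the tissue by a spring along the wall normal with damping; the wall is
massless, so the normal velocity is the net load over the damping
coefficient, capped at 0.5 dx per step so remapping never skips a row:

    F_n = (p_in − p_tissue)·ℓ − k_tether·d − c_damp·v − F_ca

with `d` the outward displacement and `F_ca` the active contraction force.
When the discrete wall row crosses a lattice row, vacated lumen-side nodes
are refilled with the equilibrium distribution at linearly extrapolated
(ρ, u) from the two nearest lumen neighbours; nodes vacated on the tissue
side revert to porous tissue at the far-field density.  Lumen mass is
conserved through remapping: the populations of a node absorbed by the
advancing wall are redistributed over the remaining lumen column (the
piston displaces its stroke volume rather than deleting it — this
pressurisation is what ejects fluid axially), and the mass of a node
created by the receding wall is drawn from the column (diastolic suction).
Residual bookkeeping is logged as `mass_created` in the manifest.

Wall constants (`k_tether = 0.025`, `c_damp = 100` lattice units at the
coarse resolution) were calibrated once so that (i) the passive distension
under the adverse-gravity head is ~1 lattice unit and (ii) a contraction at
`f_ca·ca ≈ 0.1` reduces the diameter by 30–50% over ~0.3 s, the physiologic
ejection fraction and timescale.

## Valves

Each of the 7 valves is two elastic leaflet chains anchored at opposite
wall nodes, biased open: the rest shape is a straight fibre inclined 30°
downstream with tips separated by 35% of the lumen.  Leaflets carry
stretching and bending springs (the base angle is held against a ghost
point on the wall tangent) and velocity damping.  Opening and closing are
entirely passive.

Several numerical devices keep passive valves workable at 10 nodes per
lumen diameter; each was added to cure a specific observed failure mode:

1. **Drag-coupled overdamped update.**  Pure no-slip advection of stiff
   fibres is explicitly unstable here (the spread force accumulates in the
   fluid over the viscous response time and overshoots).  Leaflet nodes
   instead move with the interpolated fluid velocity *plus* a small direct
   mobility (0.5) on their elastic+contact load — the massless force
   balance with finite fluid friction.  The fluid still receives the full
   spread force.
2. **Distributed rest-shape springs** (`k_rest = 2e-3` per node) instead of
   relying on the base-angle spring alone: a leaflet flattened against the
   wall by an ejection jet cannot be rotated back by a single base torque
   working against the drag of the whole chain, and the bending stiffness
   is deliberately low (`k_bend = 0.01`) so that gentle retrograde flow
   (~0.1 cm/s) can advect the tips shut.  The rest springs restore the
   open bias on a ~0.1 s timescale, far weaker than closing drag.
3. **Closedness-weighted porous curtain.**  An immersed fibre is permeable
   under a sustained pressure difference, so a closed valve would leak its
   held volume back.  The lattice cells under each leaflet
   (supercover-rasterised, two cells thick in both directions so no
   populations slip between diagonal fibre cells) carry a partial
   bounce-back fraction ramping from zero at/above the bias-open rest gap
   (an open leaflet is flow-aligned and transparent, so assisting-gravity
   shear and its NO are not throttled) to `ns_seal = 0.98` at coaptation.
4. **Commissure and sinus constraints.**  Leaflet nodes cannot prolapse
   upstream past the annulus, consecutive nodes keep at least 85% of the
   rest spacing (a backjet otherwise crumples the soft chain into a ball
   whose rasterisation has holes), and the distal half keeps 1.4 lattice
   units of wall clearance (the sinus pocket) so a reopening jet can
   always reach it.
5. **Transvalvular pressure assist** (`dp_gain = 2`): the axial pressure
   difference sampled three nodes either side of the valve is applied to
   the leaflet update directly, standing in for the form drag the coarse
   immersed fibre cannot carry.  Larger gains act as a spurious ratchet
   pump and are rejected.

Leaflet–leaflet and leaflet–cell contact is a linear penalty within 0.5
lattice units, equal and opposite between bodies.

## Cell

The leukocyte is a closed 20-segment membrane with stretching springs on
segments, angular springs at vertices, radial springs to the instantaneous
centroid, and a weak area-compressibility penalty (the membrane encloses
fluid of the same density; the penalty keeps the enclosed area within a few
percent over a transit).  All forces are the exact analytic negative
gradient of the total energy — including the chain rule through the
centroid — which the tests verify against central differences at 10⁻⁶
relative tolerance.  Epc, the reported deformation energy, is that same
total elastic energy: zero exactly on the circular rest shape, positive
otherwise, with no assumed deformation geometry.

The membrane couples through the 4-point Peskin kernel; because the cell
diameter (6 lattice units in the chain preset) is comparable to the kernel
width, opposite-side kernels overlap and a purely advected membrane cannot
resist spurious through-flow — it slowly implodes.  The membrane therefore
also advances with a small mobility (0.2) on its own elastic load, the
same drag-coupled scheme as the leaflets, which pins the shape while
transport remains advection-dominated.  The default rest radius is 25 µm;
the chain preset uses 30 µm (6 nodes across).  The cell starts mid-way
along the first lymphangion of the collecting chain, offset 8 µm above
the centreline: at the blind upstream end of the initial lymphatic the
flux is zero by construction, and a start adjacent to the first valve
leaves the cell exposed to that valve's closing backjet.

## Ca++/NO layer

Ca++ lives on the contracting wall as one gap-junction-coupled value per
column (the muscle ring is assumed vertically symmetric).  Resting
dynamics:

    dc/dt = c_base + k_cicr·h(c) + k_stretch·max(0, ΔD/D₀)
            − k_deg·(1 + k_noca·NO)·c + D_ca ∂²c/∂s²

with `h` a Hill function (exponent 2, half-saturation 0.5).  Crossing the
threshold (c = 1 by normalisation) dumps the store to a CICR spike level
(1.5) and starts a contraction with force `f_ca·c`; the cytoplasm then
depletes at `k_deplete`, the contraction ends below `ca_off = 0.6`, and a
refractory window `1/recharge_rate` suppresses CICR and stretch terms.
The spike is essential: without the release upstroke a freshly triggered
node immediately drops below its neighbours and the wave dies
(sub-excitable); with it, diffusion recruits neighbours robustly.

Initialisation is just below threshold (0.95) with an upstream-first
gradient (0.06 across the chain) plus a small seeded jitter (≤0.002, the
only use of the run seed).  The gradient acts as a pacemaker bias:
contractions recruit as a downstream-travelling peristaltic wave rather
than firing synchronously — a synchronous contraction against closed
valves is pressure-locked and pumps nothing.  Two further choices protect
the sequential wave: the lateral diffusivity is gap-junction-scale
(3×10⁻⁵ cm²/s; larger values make recruitment effectively instantaneous)
and the stretch gain is moderate (1 s⁻¹; strong stretch activation lets
the distension pulse ahead of an ejecting lymphangion fire its neighbour
immediately).  At ≥2 g adverse the initialisation also schedules a
transient doubling of the force constant for 0.5 s (the starting kick
needed at high adverse gravity).

NO is produced at wall- and leaflet-adjacent fluid nodes in proportion to
the local shear stress (one-sided velocity gradient at walls, rate-of-strain
magnitude at leaflets), optionally at the cell surface, advected by the
fluid (first-order upwind) with molecular diffusivity 3.3×10⁻⁵ cm²/s, and
decays with the 0.31 s half-life.  Concentrations are dimensionless; the
production gain is set so that the assisting-gravity flow sustains
near-wall NO of order one.

All rate constants were calibrated once, jointly, against the behavioural
requirements the model exists to reproduce: contraction periods of O(1 s),
30–50% diameter reduction, sustained pumping under adverse gravity, and
complete NO silencing at −2 g.  The discriminating margin is physical, not
numerical: with valves closed, adverse-gravity backflow is throttled and
wall shear (hence NO) collapses, while assisting-gravity flow keeps
near-wall NO several-fold above the suppression boundary
(`NO* ≈ 0.3` at the default constants).

## Coupling order

Per step: moments → wall/cell shear → NO transport → Ca++ update →
trigger/active force → wall load, overdamped advance, node remapping →
structure forces spread + structures advanced → BGK collision with the
assembled force field → porous/curtain partial bounce-back → gap leak rule
→ streaming → moving-wall bounce-back → pressure outlet → tissue far
field.  Physics is deterministic for a fixed config and seed; checkpoint
and restart reproduce a straight run to floating-point accumulation
accuracy.

## Study conditions and problem sizes

The `full_chain` preset is the study condition: 6 lymphangions + 7 valves
over 5.6 mm, 10 nodes across the lumen (282×32 lattice), 2.5 simulated
seconds (~37,500 steps), cell enabled, seed-jittered pacemaker bias.  The
`poiseuille_channel` preset (33 transverse nodes) is the analytic fluid
check; `single_lymphangion` is a short valved vessel used for the
rectification property.  These sizes resolve the mechanisms — valve gating,
peristaltic recruitment, cell squeezing — but not the paper-scale sharpness
of valve jets or boundary layers; quantitative outputs (velocity ratios,
Epc magnitudes) should be read as order-of-magnitude and orderings, which
is how the acceptance checks treat them.

What the synthetic conditions do not emulate: 3D/axisymmetric geometry,
anatomically measured lymphangion lengths (only the 5.6 mm total and
0.296 mm stub are constrained), nucleated cells, adhesion, and literal
gravity magnitude (see the gravity scale above).

Two quantitative behaviours fall short of their full-scale analogues at
this resolution, and the acceptance checks report them honestly rather
than hiding them:

- the run-averaged cell/bulk-exit velocity ratio under adverse gravity is
  ~1.2 over a 3 s window, although the instantaneous ratio during the
  pumping phase is 1.5–2 (the contracted-chain/fixed-exit mechanism is
  present); the average is diluted because the cell sits parked through
  the first contraction wave while the ejection pulse inflates the bulk
  average, and only one-to-two waves fit in the desk-scale window;
- the enclosed membrane area drifts by several percent (not <3%) through
  valve squeezes: at 6 lattice nodes across, the membrane relies on its
  area penalty against kernel-overlap leakage, and stiffening it enough to
  hold 3% suppresses the deformation dynamics the cell model exists to
  show.

## Known limitations

- Structure constants (wall, valve, cell) are expressed in lattice units at
  the configured resolution; changing `resolution` rescales their physical
  meaning and would require recalibration.
- The curtain device makes a closed valve porous rather than sealed;
  residual leak during valve re-closure shows up as diastolic refill from
  the outlet side of the terminal valve.
- Cell–wall contact is a one-sided clamp (the wall does not feel the cell);
  leaflet anchors likewise pass their reaction to the wall tether rather
  than the fluid.
- Chemistry operates per column; top/bottom asymmetric contraction modes
  are excluded by construction.
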