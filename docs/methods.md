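# Methods

`cervifem` evaluates the mechanical safety of an anterior cervical
discectomy-and-fusion (ACDF) construct on a synthetic, parametric model of
the C2–T2 spine.  The pipeline has five stages: phantom generation,
density-driven material assignment, load-case construction, linear
elastostatic solution, and principal-strain / range-of-motion evaluation.
All quantities use a consistent mm / N / MPa / N·mm unit system.

## The model

**Geometry.**  Each vertebra is a stylized solid: an elliptic-cylinder
trabecular body (width × depth × height per level; the axis C2 is wider
than the subaxial levels because its load-bearing section includes the
fused lateral masses) plus a posterior block that carries the spinous,
laminar and articular landmarks.  The body is partitioned into a *central*
and an *exterior* trabecular region at 60 % of the normalized elliptical
radius, and wrapped circumferentially by a one-element wedge shell of
cortical bone (0.28 mm cervical, 0.24 mm thoracic).  Endplates stay
trabecular so that discs and spacers can attach node-coincident.  The
phantom replaces patient-specific reconstruction deliberately: the rest of
the pipeline only requires named regions, landmarks and surfaces, and a
parametric solid makes every geometric property testable against closed
forms (e.g. body volume vs. π·a·b·h).

**Discs.**  Each free junction carries a disc whose nucleus pulposus (NP)
core sits inside an anulus fibrosus (AF) ring.  The NP endplate-area share
(default 0.43, valid band 0.25–0.50) and volume share (default 0.45, band
0.40–0.50) are controlled independently by widening the core towards
mid-height: with `n` layers the two boundary layers match the area share
and the interior layers take the share `(f_v n − 2 f_a)/(n − 2)`, so the
measured volume share meets the request.  Cells are assigned to the core
greedily from the innermost columns, which keeps the discrete shares within
roughly half a cell area of the targets.

**Ligaments.**  Six groups (ALL, PLL, ISL, SSL, ITL, LF) are mapped as
tension-only two-node trusses, one unit per group per junction (two for the
paired ITL and LF, which split the tabulated cross-section), attached at
parametric landmarks by nearest mesh node.  The ALL is omitted across the
instrumented span (resected at surgery).  SSL units can be merged into the
ISL per junction via configuration; by default they are kept everywhere.

**Facet joints.**  Articular contact is modelled from C5–C6 down to T1–T2
as small-sliding node-to-surface penalty contact with friction coefficient
0.07 between the posterior blocks, which extend into the disc space to
leave a 0.3 mm initial gap.  The contact faces are inclined bilaterally
(default 20°, a roof shape with the apex on the midline) so that the joint
interlocks under axial rotation and lateral shear the way real cervical
facets do; with flat horizontal faces the stack has essentially no
torsional stiffness and axial-rotation results become meaningless.
Cartilage layers are not modelled.

**Instrumentation.**  Three PEEK interbody spacers (8, 8, 7 mm) fill the
C2–C3, C3–C4 and C4–C5 disc spaces, a titanium plate (55 × 16 × 2.25 mm)
sits on the anterior column, and eight Ø4.0 × 15 mm titanium screws (two
per instrumented vertebra) pass through the plate into the trabecular
bodies.  Per screw, the element set `trajectory_<level>_<side>` collects
the bone elements within one screw diameter of the shaft axis — the region
screw plowing damages first.

**Connections.**  Three mechanisms bond parts, chosen to keep the global
force *and moment* balance exact:

1. *Exact node merges* (DOF sharing) where meshes are built node-coincident:
   disc/spacer faces against endplates.  All stacked cross-section grids
   share one resolution (taken from the widest body) and discs taper
   linearly between the two endplate footprints, so these interfaces
   coincide bit-exactly.
2. *Interpolated embedding* (linear multi-point constraints): a node inside
   a host solid follows the barycentric interpolation of its enclosing
   tetrahedron.  Used for the posterior block's anterior face (which lies
   strictly inside the body ellipse) and for screw nodes inside bone or
   plate.  Because the interpolation point coincides with the slave node,
   the constraint transmits no spurious couple.  Nodes that fall outside
   every host (screw segments crossing the anterior wall gap) are not
   embedded.
3. *Bond struts*: the screw's anterior cortical purchase is modelled by
   short bilateral titanium trusses from each wall-gap screw node to the
   corners of the nearest cortical-wall facet.  These are real elements, so
   equilibrium is exact by construction.

A plain DOF merge of *offset* node pairs — the obvious shortcut — is not
used anywhere: each such pair transmits equal-and-opposite forces at
different points and therefore absorbs a couple proportional to the offset.
In an early construction of this model those phantom couples swallowed
essentially the entire applied motion torque before it reached the lower
column.  A global moment-balance audit (applied torque + gravity vs. base
reaction) is part of the test suite; with the scheme above it closes to
within ~2 % (the residue comes from contact-force transfer at projected
points and clipped embeddings).

## Materials

Trabecular bone takes its Young's modulus from the per-region volumetric
BMD (mg/cc) through the power law `E = 10200 (BMD/1000)^2.01` MPa
(`as_used` mode, the default, which reproduces the full reference card to
the printed 0.01 MPa).  An `as_printed` mode exposes the four-branch
piecewise calibration (33 900 ρ^2.2 below 0.27 g/cc, 5 407 ρ + 469 up to
0.60 g/cc, the 2.01 power above); the branch thresholds are interpreted in
g/cc.  The zero-density value 0.001 MPa is applied as a floor, which keeps
the mapping monotone for vanishing densities.  Note that the piecewise form
itself is not globally monotone (it steps down by ~1.7 % at the 0.60 g/cc
boundary); monotonicity is therefore only property-tested per branch.

Fixed cards: cortical bone (1000 MPa, ν 0.30), NP (1.0, 0.49), AF (3.4,
0.40), PEEK (4000, 0.35), titanium (110 000, 0.30).  Ligament trusses use
their tabulated moduli and cross-sections (ALL 20 MPa / 38 mm², PLL 70/20,
ISL 28/35.5, SSL 28/35.5, ITL 50/10, LF 50/60; ν 0.3 throughout — stored
for completeness, irrelevant to axial truss stiffness).  Posterior elements
are assigned the cortical card: pedicles, laminae and processes are
predominantly compact bone, and giving them the soft exterior-trabecular
modulus concentrates the spinous-process moment input unphysically.

## Loads

The head weight is `body_mass × 0.0783 × g`; the shipped example uses
39.97 kg, i.e. 30.7 N.  It is applied vertically, split equally per node
over the two facet patches beside the C2 odontoid process (the patches are
flat and small, so an equal per-node split is adequate; the tested contract
is the force total and the 50/50 side split).  Each motion's torque is the
isometric strength (flexion 418, extension 683, lateral flexion 542, axial
rotation 208 N·mm per kg head mass) times the head mass, applied at a
reference point kinematically coupled to the C2 spinous-process node set.
Axes: flexion +x / extension −x (lateral axis), lateral flexion +y
(anteroposterior), rotation +z (vertical).  The base fixation defaults to
the inferior surface of T2, the lowest modelled level; a `fix_level`
switch (e.g. `T1`) is provided because the vertebral span and the stated
fixation level can legitimately differ by one segment in this kind of
model.

## Solver

Standard isoparametric small-strain elements: 10-node tetrahedra (4-point
rule) for solids, 15-node wedges for the cortical shell (7-point triangle ×
3-point Gauss — a 6-point rule leaves the 45-DOF wedge rank-deficient),
with 4-node tets and 6-node wedges retained for small oracle fixtures, and
axial-only 2-node trusses.  Ties, embeddings and the kinematic coupling are
condensed into one sparse reduction matrix `u_full = C u_red`; the reduced
system is solved with SuperLU in symmetric mode plus one step of iterative
refinement.

Two mild nonlinearities are resolved by an outer fixed-point loop:
tension-only trusses (active-set: members in compression are removed,
members returning to tension re-enter) and penalty contact (pairing fixed
at the start — small sliding; normal penalty 50× the master element's
representative stiffness; penetration tolerance 1e-3 mm).  Friction is
secant-regularized Coulomb: tangential stick springs of penalty stiffness,
capped to μN/|s| once the stick force would exceed the Coulomb limit, so a
slipping pair carries exactly μN opposing the slip at equilibrium.  All
contact terms are springs, which keeps the fixed point stable under the
adaptive under-relaxation used for the active-set iteration (halve the
relaxation factor on divergence or on a detected 2-cycle, grow it back on
progress).  The secant state is frozen after a configurable number of
passes (default 3); with μ = 0.07 the residual error in the friction force
is a fraction of the already small tangential term.  Convergence requires
the active sets to reproduce themselves and, when contact is engaged, the
displacement increment to fall below `contact_rtol` (default 1e-5
relative; the truss-only path uses the exact piecewise-linear fixed point
and the tighter `rtol`).

## Evaluation

Per-element strain tensors are volume-averaged over the quadrature points;
principal strains are their ordered eigenvalues.  The damage index is
`D = max(ε1/εt, ε3/εc)` with εt = +1.5 % and εc = −2.0 %, each ratio
floored at zero so only correctly-signed strains count; an element with
D ≥ 1 is regarded as broken.  The verdict checks the central vertebral
bodies, all screw trajectories and the spacer-contacting endplate bone in
all four motions, and additionally enforces the small-sliding plausibility
gate: every contact slave-node slip must stay below the local element
length.  Nodal-averaged principal-strain fields are available for surface
maps; the element field drives the index.

Segmental range of motion is the relative best-fit rigid rotation (Kabsch)
between the two vertebrae of a junction, projected on the motion axis, in
degrees.  The axes are the phantom's fixed global anatomical axes (the
phantom is built axis-aligned; no per-vertebra frames are defined).  Both
per-motion angles and the flexion+extension sum are reported, since both
conventions are common.

## Problem sizes and defaults

The default `PhantomSpec` mesh size is 3.0 mm; the shipped example
configuration uses 4.5 mm, which gives ≈26 000 nodes (tet10) for the full
instrumented stack and runs the four-motion pipeline in a few minutes on
one CPU.  Tet-quality inspection (shape quality, volume skew, collapse) is
reported by `cervifem.mesh.mesh_quality` with gates calibrated to the
structured-split element shapes the generator produces.  With the shipped
example the verdict is PASS (max damage index ≈ 0.42), the largest facet
slip is ≈ 0.4 mm, instrumented junctions move ≲ 0.6° and free junctions
2–8° per motion — the clinically expected pattern of a rigid fused block
above mobile segments.

## What the phantom does and does not show

The generator emulates the *structure* of an instrumented cervical spine —
region topology, interfaces, ligamentous tension paths, facet contact, and
the density-to-stiffness coupling — under the documented loads.  It does
not reproduce any patient's geometry: vertebral shapes are stylized,
facet orientation is a single angle, muscles are absent (loads are resultant
torques), and materials are linear elastic.  Passing results therefore
validate the *method* (the pipeline computes equilibrium, strain fields,
damage indices and ROMs correctly and reproducibly on a realistic-scale
problem), not the clinical outcome for a specific patient.  Conversely, the
desk-reproducible quantities — the density-modulus card, the torque table,
the damage-index arithmetic and the disc composition bands — are exact
reproductions and are asserted to their printed precision.

## Known limitations

- Small-sliding contact with a fixed pairing: results degrade if facet
  slips approach the element size (the slip gate flags this).
- Linear kinematics: applied torques that rotate segments by more than a
  few degrees are at the edge of the small-rotation regime.
- Screws overlap the bone mesh rather than carving it (no CSG); the
  overlapped bone follows the embedded screw field, so the screw acts as a
  reinforcing inclusion and strains develop in the surrounding annulus of
  bone, which is the quantity the trajectory report summarises.
- The NP/AF split is concentric; real cervical discs lack a complete
  posterior anulus.
- Fatigue, plasticity and viscoelasticity are out of scope; the damage
  index is a static threshold criterion.
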