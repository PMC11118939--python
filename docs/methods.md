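# Methods

`spinefe` simulates quasi-static axial compression of a human L2–L4
lumbar segment and asks how two age-related degeneration mechanisms —
osteoporotic change of the vertebrae (trabecular density loss, loss of
the cortical–trabecular bond) and intervertebral disc degeneration
(stiffer, decompressed nucleus; stiffer annulus) — change the segment's
load capacity, disc deformation, and buckling stability.

## The model

### Geometry (synthetic stand-in for a CT pipeline)

No patient geometry is shipped; the mesh generator produces an idealized
parametric segment whose dimensions follow the anthropometric values the
study is built around:

| quantity | default | unit |
|---|---|---|
| vertebral body width × depth × height | 40 × 33 × 30 | mm |
| cortical wall / endplate thickness | 0.5 / 0.5 | mm |
| mid-height waisting of the body | 10 | % |
| disc height | 10 | mm |
| nucleus area fraction | 0.40 (of 0.30–0.50) | – |
| annulus fibre shells | 2 × 0.75 mm at ±30° | – |
| imperfection amplitude | 0.04 (0.1% of width) | mm |

Cross-sections are butterfly meshes (square core blended into quad rings
out to the elliptic boundary), extruded into 8-node hexahedra; one ring
interface is placed by 1-D root solving so the enclosed area matches the
nucleus fraction exactly. Vertebra–disc interfaces share nodes. The
cortical wall is a separate sheet of 4-node shells spanning the wall
between the endplate interfaces, tied node-to-node to the solid surface;
degeneration grading deactivates the lateral ties (debonding) while the
edge rows on the endplate boundaries stay tied, so the load path through
the endplates survives. Posterior elements are simplified to a stiff
block extruded from the posterior wall (shared nodes); six ligament
groups (ALL, PLL, CL, LF, ISS, SSL) are 2-node tension-only links
between conventional landmark anchors. Ligament cross-sections are not
reported anywhere authoritative; configurable defaults of 20–40 mm² are
used (they are slack under pure compression and carry no load here).

A seeded lateral-wall imperfection (smooth Fourier series in the wall
angle, sin(πζ) through each body height, amplitude ≤ 0.1% of the body
width) breaks the symmetry so wall buckling can be realized by a
discrete model.

### Materials

* Cortical shell: orthotropic elastic (E_xx = E_yy = 2667, E_zz = 8000,
  G = 1026/1539/1539 MPa), von Mises yield at 64 MPa with linear
  isotropic hardening (H defaults to 5% of E_zz; the source model states
  hardening but no modulus).
* Trabecular core: orthotropic elastic with the density power law
  E_zz [MPa] = 4730·ρ^1.56 (ρ in g/cm³) and E_xx = E_yy = 0.1·E_zz;
  shear moduli per the published card at the two reference densities.
  The published Poisson ratios are interpreted as major ratios referred
  to the stiff longitudinal direction — read the other way the
  osteoporotic card is thermodynamically inadmissible (indefinite
  compliance).
* Endplates E = 50/ν = 0.4, posterior block E = 3500/ν = 0.25.
* Nucleus pulposus: E = 1 MPa, ν = 0.4999 healthy; E = 1.66, ν = 0.4
  degenerated.
* Annulus ground substance: Neo-Hookean, C10 = μ0/2, D = 2/K0 with
  μ0 = E/2(1+ν), K0 = E/3(1−2ν) — the printed (1+2ν) variant of the bulk
  relation does not reproduce the published (C10, D) pairs and the
  corrected relation reproduces both exactly. Healthy E = 1.4,
  degenerated E = 6.3 MPa at ν = 0.40 (C10 = 0.25/1.13, D = 0.86/0.19).
* Annulus fibres: two membrane layers (outer surface, and the
  nucleus–annulus interface ring), each a smeared ±30° cross-ply with
  layer modulus 500 (external) / 300 (internal) MPa.

### Degeneration grades

| grade | trabecular ρ [kg/m³] | bond | nucleus | annulus |
|---|---|---|---|---|
| 1 | 300 | bonded | 1 / 0.4999 | C10 0.25 |
| 2 | 100 | bonded | 1 / 0.4999 | C10 0.25 |
| 3 | 100 | unbonded | 1 / 0.4999 | C10 0.25 |
| 4 | 100 | bonded | 1.66 / 0.4 | C10 1.13 |
| 5 | 100 | unbonded | 1.66 / 0.4 | C10 1.13 |

Debonding defaults to the L3 wall only (the failure analysis is
L3-centric); a config switch widens it to all three vertebrae.

### Discretization and element technology

Solids are 8-node trilinear hexahedra in a total-Lagrangian setting
(Green–Lagrange strain / 2nd Piola-Kirchhoff stress, 2×2×2 Gauss).
Orthotropic and moderately compressible isotropic cards use St.
Venant–Kirchhoff; the annulus uses the Neo-Hookean model above; the
near-incompressible nucleus is realized as a compressible Neo-Hookean
with the card's small-strain moduli and the volumetric energy evaluated
at the element-mean dilatation (mean-dilatation B-bar). Two numerical
reasons: trilinear hexes lock volumetrically at ν → 0.5 without B-bar,
and an SVK bulk term of 1667 MPa acting on the Green–Lagrange trace is
not robust at the ~10% compressive strains the discs reach (Newton
stalls on a positive-definite tangent).

The cortical wall is a flat-facet shell: total-Lagrangian membrane (the
quadratic Green-strain terms in all three local displacement components,
so membrane force couples to out-of-plane deflection and the wall can
buckle), Mindlin bending with one-point transverse shear plus a 0.2%
full-integration stabilization, and a small drilling penalty. Membrane
plasticity uses a plane-stress von Mises return solved by bracketed
bisection on the plastic multiplier (the anisotropic elastic operator
rules out the isotropic closed form); the algorithmic tangent is built
by central differences of the return map at the active points. Bending
stays elastic. Fibre membranes are small-strain membranes on solid-node
faces: a membrane with zero bending stiffness would wrinkle at the
element scale under the compressive stress the disc wall sees, so the
out-of-plane coupling is deliberately dropped; they act purely as
in-plane (hoop and axial) reinforcement.

Ties are node-to-node equal-translation couplings eliminated through a
dof-representative map; for the coincident pairs used here this is
exactly the force-distributed master–slave coupling, and a test checks a
tied stack against a conforming mesh to 1e-8.

### Solution

Displacement control: the L4 base is fixed, the axial dofs of the L2 top
endplate are driven to −2.5 mm over a pseudo-time t̄ ∈ [0,1] in 50
uniform increments (configurable). Per increment, inexact Newton with:
a linear-extrapolation predictor; LU-preconditioned GMRES on the current
consistent tangent (the sparse LU is refreshed only when the Krylov
solver reports drift, SuperLU/COLAMD); a backtracking line search that
rejects diverging steps; consistent tangents skipped while the trial
plastic state is far from the committed one (the tangent at a wildly
plastic transient iterate destabilizes the iteration); residual
tolerances rel 1e-6 / abs 1e-8 N; up to 4 increment bisections, after
which the run returns the partial history flagged — under displacement
control that is itself a result (loss of static load capacity).

### Stability analysis

* Plastic onset: first increment with equivalent plastic strain > 1e-8
  in the cortical shell; reports t̄, F, and max cortical von Mises.
* Bifurcation: the lateral displacement u_x at probe point A (the
  lateral-most L3 wall node at mid-height) grows essentially
  proportionally while the response is stable. The detector fires when
  the incremental rate du_x/dt̄ jumps by a factor J (default 10)
  relative to the initial secant or changes sign, with a minimum visible
  amplitude of 0.02 mm, and interpolates the crossing between interval
  midpoints so the result is insensitive to the increment count. On a
  pre-critical amplification hyperbola a factor J fires at
  P/P_cr ≈ 1 − 1/√J; the Euler-column verification uses J = 100, which
  places the trigger within a few percent of the critical point.
  Post-buckling is "unstable" when the lateral excursion subsequently
  shrinks while the force plateaus or drops.
* Linearized buckling: smallest positive λ with K_e + λ·K_σ singular at
  a converged reference state (default t̄ = 0.1), via shift-free Arnoldi
  on K_e⁻¹(−K_σ); critical load = λ × reference load. Verified against
  π²EI/L² for a pinned hex column to about 1%.
* Classification: plasticity-limited / buckling-limited / mixed /
  elastic-stable from the order of onset and bifurcation and the sign of
  the post-event force slope.

### Outcome metrics

Bulge (max outward radial displacement of a lateral region, measured
relative to the body's mean lateral translation), shear (difference of
mean horizontal displacement between a disc's cranial and caudal
interfaces), shortening (decrease in mean axial gap), F_max, and percent
changes via 100·(value/baseline − 1). The mesh-convergence harness runs
the same model at decreasing element sizes and applies the
successive-refinement rule: converged when all tracked summaries differ
by no more than 5% between successive resolutions (the boundary value
passes).

## Problem sizes

The grade sweep runs at 3 mm target element size (≈ 4500 hexahedra,
≈ 1000 shells/membranes, ≈ 21k dofs) and 50 increments — a deliberate
desk-scale setting chosen so a five-grade sweep completes in minutes on
one core; mesh-convergence checks run a single vertebra at 3 and 2 mm.

## What the synthetic generator does and does not emulate

It reproduces the reported anatomy (dimensions, components, layup,
ligament topology) and the degeneration scenarios exactly, but not
patient-specific shape: no lordotic curvature, no facet articulation, no
regional density variation, and the posterior elements are a single
stiff block. Passing tests therefore validate the mechanics pipeline
under idealized geometry, not patient-specific response prediction.

## Known limitations

* With the published constitutive cards, the discs — not the vertebrae —
  dominate the axial compliance of the idealized segment: a 10 mm disc
  with a 1.4 MPa annulus, a 1 MPa (even incompressible) nucleus and two
  thin ±30° fibre membranes has an axial stiffness of ≈ 0.3–0.6 kN/mm
  (a ring-pressurization hand estimate and the FE agree). The segment's
  computed capacity at 2.5 mm compression is therefore at the lower end
  of the physiologic range, the cortical wall stays far below yield, and
  force differences between grades are driven mainly by the disc cards
  (the degenerated annulus is ~4.5× stiffer than the healthy one, so
  grades 4–5 carry more, not less, load at equal shortening). Capacity
  values and grade orderings should be read with that in mind.
* Quasi-static, displacement-driven, no muscle forces, no contact
  closure after debonding, no poro/viscoelasticity, bending of the
  cortical shell stays elastic, fibre families resist compression as
  well as tension (smeared cross-ply).
* 8-node hexahedra with B-bar instead of quadratic solids; the
  convergence harness quantifies the residual mesh sensitivity.
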