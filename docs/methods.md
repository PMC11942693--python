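# Methods

## Model

All materials are isotropic, homogeneous, linear elastic. Two physics are
solved on the same tetrahedral mesh:

1. **Steady-state heat conduction**, ∇·(k∇T) = 0, with Dirichlet data only:
   10 °C on every node of the polymerizing materials (composite, cement),
   36 °C on the external model surface and on the HAP insert. This is not a
   thermal problem per se — it is the *shrinkage analog*: the temperature
   drop ΔT = T − T_ref (T_ref = 36 °C) carries a thermal strain
   ε_th = αΔT·(1,1,1,0,0,0) that emulates polymerization contraction. Because
   the field is fully Dirichlet-pinned on the shrinking materials, the
   solution is independent of a uniform scaling of k; k defaults to 1
   everywhere.
2. **Linear elastic statics** with constant-strain tetrahedra:
   K u = f_th + f_mech, σ = C(Bu − ε_th). Phase 1 applies f_th only; phase 2
   applies f_th plus a uniform pressure with resultant 2000 N along −z over
   the occlusal facet set, in a single linear solve. For a linear model this
   equals the sequential two-step load path by superposition; the equality
   phase2 = phase1 + mechanical is asserted as a test, not assumed.
   The healthy tooth has no shrinking material and is solved
   mechanical-only.

### Shrinkage calibration

The linear expansion coefficient of composite and cement is set by inverting
the free-shrinkage relation (1 + αΔT)³ = 1 − S at the default target
S = 0.037 and ΔT = 26 °C, giving α ≈ 4.803·10⁻⁴ °C⁻¹. Both polymerizing
materials share one α. On an unconstrained body this reproduces S exactly
(constant-strain elements are exact for uniform strain); inside a bonded
cavity the measured contraction is smaller because the walls constrain the
restoration — the in-situ rates the pipeline reports per scenario quantify
exactly that constraint. Tissues and the insert default to α = 0 so the
analog is the only strain source; literature coefficients (enamel
11.4·10⁻⁶, dentin 8·10⁻⁶, HAP 13.3·10⁻⁶ °C⁻¹) are available as an opt-in
mode for users who want thermally active tissues.

### Materials

E (MPa) / ν: pulp 6.8/0.45, dentin 18600/0.31, enamel 84100/0.30, bone
1370/0.30, cement 4000/0.35, composite 16600/0.24, HAP insert 100000/0.28.
The periodontal ligament has no published record in this model family; a
literature-typical soft record (E = 50 MPa, ν = 0.45) is supplied and
configurable. The stiffness tensor is the standard isotropic Voigt form
(order xx, yy, zz, yz, xz, xy, engineering shear), positive definite for
every record since ν < 0.5.

## Synthetic geometry

The geometry is an idealized stand-in for a scanned right mandibular first
molar: an elliptic cylinder (semi-axes 5 and 5.5 mm, height 21 mm, flat
occlusal surface) with an enamel crown shell (8 mm crown height, 2.5 mm
occlusal / 1.5 mm lateral enamel), an elliptic-cylinder pulp chamber
(semi-axes 1.5 × 1.8 mm, z ∈ [2, 12] mm), a 0.25 mm PDL shell below the
crown, and a 16 × 17 × 14 mm bone block. The cavity is an axis-centered
5.5 mm diameter cylinder. Insert diameter is 4.7 mm; the lateral cement gap
is therefore (5.5 − 4.7)/2 = 0.4 mm (the printed trio of diameters is
mutually inconsistent by 0.2 mm, and the cavity and insert diameters are
taken as authoritative); the cement floor is 0.5 mm and the composite cap
2.0 mm. Cavity depths are not free parameters: depth = cap + floor + insert
thickness, i.e. 4.2 mm (small, 1.7 mm insert) and 7.2 mm (big, 4.7 mm
insert), so each composite-only control shares its cavity with its insert
counterpart exactly. The big cavity floor (z = 13.8 mm) stays above the pulp
roof (z = 12 mm), emulating a deep restoration at the root-canal entrances.

What the stand-in deliberately drops: cusp morphology, multi-rooted root
anatomy, tooth inclination, and the scan-derived surface detail. Absolute
stress magnitudes are therefore *not* comparable to anatomy-derived models
(flat occlusal loading spreads the force very differently from cuspal
contact); only geometry-independent quantities (free contraction rate,
equilibrium) and within-model comparisons (insert vs control directions,
percent decreases) are meaningful, and only those are asserted.

## Meshing

A structured background grid (spacing h, rounded per axis to span the
bounding box exactly) is classified at cell centers; kept cells split into
6 positively oriented tetrahedra (Kuhn split). Boundaries are stair-stepped:
no snapping, hence no sliver elements, perfect determinism, and a geometric
error that shrinks with h (domain volume converges to the Monte-Carlo
reference within 5% at h = 0.5). Element region = classification of the tet
centroid (fallback: parent cell). The default h is a single 0.6 mm
everywhere — chosen as the finest uniform size whose full five-scenario,
nine-solve study stays a few-minute desk job (≈ 120k elements, ≈ 68k dofs
per scenario); h is a first-class config knob and the refinement-stability
test checks the default regime (max displacement moves < 10% from h = 1.0
to h = 0.5). The 0.4 mm lateral cement gap is sub-grid at the default h:
lateral cement is captured only where tet centroids land in the ring, while
the 0.5 mm cement floor and 2.0 mm cap are resolved. This biases cement
volume low at coarse h but leaves the study's comparisons intact, since the
dominant effect is the shrinking-volume difference between scenarios.

Element quality is reported as Q = 1 − V/V_reg(ℓ_rms), where V_reg(ℓ) =
ℓ³/(6√2) is the regular-tet volume at the element's RMS edge length,
clamped to [0, 1]: 0 for the regular tetrahedron (the regular tet maximizes
volume at fixed RMS edge), approaching 1 for degenerate shapes. This keeps
the familiar 0-ideal/1-degenerate Jacobian-style convention of commercial
pre-processors while being fully specified; all Kuhn tets score ≈ 0.343.

## Numerical choices

- Constrained solves: fixed dofs eliminated by reduction, SuperLU
  factorization with symmetric-pattern ordering (`MMD_AT_PLUS_A`); one
  factorization per scenario serves all its load cases. Reactions are
  recovered as K u − f on the constrained dofs and balance applied loads to
  machine precision (asserted at 10⁻⁶ relative).
- Free-floating fixtures (no supports): the singular system is regularized
  by Lagrange multipliers on the six rigid-body modes; for self-equilibrated
  loads (any pure thermal load) the multipliers vanish and the solve is
  exact, with no constraint-induced stress.
- Supports: default = all nodes on the bone-block lateral faces ("full");
  a "simple" mode fixes the z = 0 base for fixtures.
- Occlusal load: boundary facets with outward normal within 10° of +z in
  the top h-band; uniform pressure F/ΣA, each facet contributing pA_f/3 per
  node, so the resultant is exact by construction.
- Stress is per-element (constant strain); maxima are taken over element
  values, never over extrapolated nodal values. Quartiles use linear
  interpolation between order statistics. Percent decrease is signed,
  100·(control − insert)/control, with increases flagged rather than
  silently reported as magnitudes.
- Contraction rate: default method sums exact deformed tet volumes
  (x + u); a cylinder-fit method (mean radial displacement of the lateral
  surface, mean axial displacement of top/bottom) is reported alongside and
  agrees within 10% on the free-cylinder fixture.
- Degenerate inputs: non-positive element volumes raise before any quality
  or stiffness computation; an empty region group reports "absent", not
  zero; a failed scenario is recorded and does not abort the study.

## What the tests do and do not show

The verification suite is analytic: patch test (constant stress to 10⁻⁸),
series-bar compliance (1%), free-shrinkage exactness, dense-assembly oracle
equivalence, discrete maximum principle on the temperature field, global
equilibrium, superposition. The study-level assertions are directional
only: with inserts, phase-1 displacement maxima drop in enamel, dentin and
restoration; phase-2 peak enamel stress drops; and the mean dentin stress
within 0.5 mm below the deep cavity floor drops. Passing these on the
idealized geometry supports the mechanism (less polymerizing volume → less
shrinkage load → relaxed tissues) but does not validate absolute stress
magnitudes for any real tooth.

## Known limitations

Perfect bonding everywhere (no adhesive failure or debonding), no cure
kinetics or viscoelastic stress relaxation in the composite, no contact or
geometric nonlinearity, no fatigue or thermal cycling. Linear (not
quadratic) tetrahedra: peak stresses at re-entrant stair-step corners are
mesh-sensitive, which is another reason maxima are compared only across
scenarios at identical h, never in absolute terms.
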