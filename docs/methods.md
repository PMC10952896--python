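# Methods

`sporomech` models the spore capsule (sporangium) of the earliest land
plants as a thin, cellularized pressure vessel and asks what its shape and
cell pattern imply for spore dispersal: how much cavity pressure the wall
tolerates before tearing, whether stress funnels toward the apical
dehiscence site, and how organs of different morphotypes spread across a
dispersal fitness landscape.

## Shell construction

A specimen is a single epidermal cell layer enclosing the sporangial
cavity.  The outer surface is a generalized surface of revolution about
the longitudinal axis **X** = (1, 0, 0): a closed cross-section contour
(an ellipse with flattening factor *f*) is scaled at each height by a
radius profile *r(x)*.  Four morphotype profiles are provided — spherical,
fusiform (prolate spindle), discoidal (oblate lens, short along X) and
helically twisted — plus a cylindrical test body.  Profiles are truncated
near the base to leave the attachment opening (12% of the height by
default), which is later closed by a basal membrane.

Cells are a rows × columns grid in (meridian arc length, azimuth)
parameter space.  Row and column widths receive multiplicative lognormal
jitter (σ = 0.15 by default, 0.25 for the discoidal preset, seeded), and
with fourfold symmetry the column pattern of one quadrant is tiled four
times — both features mirror the fossils.  A file tilt θ shears the column
boundaries so that cell long axes make the angle θ with the organ axis
(dθ/ds = tan θ / r along the meridian, radius floored near the poles); the
twisted preset uses θ = 35°, inside the 30–40° range measured on helical
fossil capsules.  The loft grid follows the cell grid: rings sit on the
(jittered) row boundaries, contour samples on the column boundaries, each
subdivided to near-square faces, and the quad diagonals alternate in a
checkerboard.  The checkerboard matters: a uniform diagonal direction
makes the discrete shell weakly chiral and produces a spurious
height-linear torsion of order 0.02°/μm under pressure — the same order as
the genuine file-tilt signal.

Conditioning mimics the preparation of traced-and-reconstructed surfaces:
cell-boundary vertices are relaxed three times by neighbour averaging
(displacements confined to the surface tangent plane, transverse to the
boundary, and rejected if they would flip, shrink below 30% area, or
worsen a triangle past aspect ratio 2.5); triangles with aspect ratio
above 2 (longest edge over twice the inradius, normalized so equilateral
scores 1) are merged with a same-cell neighbour and retriangulated along
the better diagonal, three passes.  On a sheared loft this removes ~95% of
high-aspect triangles.

The labeled surface is extruded inward by the wall depth (8 μm, the cell
depth seen in fractured charcoalified material): inner faces are offset
copies along area-weighted vertex normals, anticlinal walls connect the
two layers along cell boundaries and rims, and every cell becomes a
watertight prism-like compartment.  Adjacent cells share one anticlinal
wall, so equal turgor on both sides cancels there — only outer, inner and
rim faces carry net turgor load.  A triangle fan closes each open rim of
the inner surface; these basal membrane faces are load-bearing but
excluded from all stress statistics.

### Preset sizes

Organs are sub-millimetre (300 μm spherical, 450 × 180 μm fusiform,
140 × 320 μm discoidal, 400 × 150 μm twisted) with epidermal cells of
roughly 18–40 μm — the size range visible in the fossils these shells
stand in for.  Cell size is a real constraint, not a free dial: with cells
approaching 70 μm the turgor-driven bulging alone pushes the top stress
percentile past the 30 MPa tensile strength before any cavity pressure is
applied, a regime the fossil record excludes.

## Membrane mechanics

Each triangle is a constant-strain membrane (no bending stiffness) of
thickness *t* = 0.5 μm — the cell-wall material itself, a standard value
for plant epidermal walls — with a St. Venant–Kirchhoff plane-stress law,
E = 100 MPa and ν = 0.3.  Kinematics are fully nonlinear: the deformation
gradient is taken per element against its reference tangent frame, the
Green strain drives the 2nd Piola–Kirchhoff stress, and reported stresses
are Cauchy (σ₃ = 0 through-thickness).  Loads are follower pressures
integrated over deformed face areas: every cell compartment carries the
turgor pressure (0.5 MPa turgid, 0.001 MPa dried) on its boundary with
outward orientation, and the cavity pressure acts on the inner surface
plus the basal membrane.  Net force and torque of these loads vanish
identically on closed compartments, so the shells float freely: no
Dirichlet constraints exist (point constraints create artefactual stress),
and rigid translations/rotations are projected out of the motion at every
iteration instead.

Equilibria are found by semi-implicit dynamic relaxation: a mass-scaled,
damped pseudo-dynamic system stepped with backward-Euler treatment of the
damping, plus kinetic-energy damping (velocities are zeroed whenever the
kinetic energy peaks).  Nodal pseudo-masses are twice the per-node
membrane stiffness estimate, giving a unit stable time step; on divergence
the masses quadruple and the load step restarts.  Convergence is declared
when the residual force norm falls below 10⁻³ of the applied load norm
(with an absolute elastic-force scale as the floor in the unloaded limit).
Cavity sweeps ramp the pressure 0 → 1 MPa in 0.01 MPa increments, each
step warm-started from the previous state; the drying comparison solves
the turgid (cells 0.5 MPa, cavity 0.2 MPa) and dried (cells 0.001 MPa)
states of the same shell.

Verification: an inflated thin sphere (R = 200 μm, t = 8 μm, p = 0.2 MPa)
reproduces the Laplace stress pR/2t within 3%, a capped cylinder matches
pR/t (hoop) and pR/2t (axial) within 5%, the discretization error at least
halves from icosphere level 3 to 4 (the element converges between first
and second order on the uniform sphere), and solutions are invariant under
rigid rotation of the input to below 10⁻⁶ MPa.

### Finite-strain rupture of the benchmark sphere

For the thin sphere with R = 500 μm, t = 8 μm and tensile strength
σ_y = 30 MPa, the small-strain closed form predicts rupture at
p = 2tσ_y/R = 0.96 MPa.  At 30 MPa the material is at ~35% strain, where
radius growth and wall thinning soften the pressure resistance: solving
the St. Venant–Kirchhoff sphere exactly (p = 2t₀S/(λR₀) with
S = E(λ²−1)/(2(1−ν)) and Cauchy stress S/λ₃) puts rupture at 0.70 MPa,
and the FEM lands on 0.70 as well.  The discrepancy with the linearized
estimate is a property of finite-strain mechanics at this stress-to-
modulus ratio, not of the discretization; both failure criteria coincide
there (equibiaxial state), as they should.

## Failure and rupture

Two criteria bracket the unknown wall behaviour: von Mises (ductile,
hydrated walls) and maximum principal stress (brittle, dry walls).
Rupture pressure is the smallest sweep pressure at which the
ceil(0.01·n)-th largest criterion stress among non-membrane elements
reaches the tensile strength (default 30 MPa; a 20–40 MPa range is swept).
The top-percentile rule exists to suppress single-element artefacts; note
that at desk scale (3–6 × 10³ elements) the percentile still contains a
few tens of elements, so junction-corner stresses in the anticlinal walls
participate — another reason realistic cell sizes matter.

The stress-assisted-rupture score measures apical localisation at the
rupture state: elements inside the elliptical cylinder about X with
semi-axes (max y)/2 and |min z|/2 (coordinates centered on the cavity
centroid), in the upper half of the X range, split into inner and outer
surfaces keeping the side with the larger mean von Mises stress; the score
is that apical mean minus the organ-wide mean.  Positive values mean the
morphology funnels stress to the apex.  Both halves of the ambiguous
geometric selection ("axes maxy/2, minz/2"; "superior" as the upper half
of the X extent) are fixed here as stated; the synthetic discoidal shells
score ≈ +4 MPa and the helical ones ≈ −7 MPa, reproducing the sign
pattern reported for cooksonioid versus twisted fossils.

Stress heterogeneity is the population coefficient of variation of the
per-element von Mises stress.  On the spherical specimen it settles, once
organ-level stress dominates the turgor-bulge pattern (≳ 0.15 MPa), onto a
plateau varying by less than 10% up to rupture, and sits well below the
fusiform specimen's CV at matched pressures.

## Morphometrics

All descriptors use principal-component extents (square roots of
covariance eigenvalues — length-like, so a 2:1 cell gives anisotropy 2):
cell anisotropy 2·PC1/(PC2+PC3), cell twist acos|PC1·X| in degrees, organ
sphericity (area of the volume-equivalent sphere over the cavity area),
and flatness (PCl_y + PCl_z)/(2·PCl_x) with PCl_x the extent along X and
the transverse extents taken as principal extents of the transverse
projection (making the measure invariant under rotations about the organ
axis).  Cell measures use area-weighted face centroids of each watertight
compartment; cell volumes come from the divergence theorem over signed
compartment faces.  Attributes are measured on the turgid state (cells at
0.5 MPa, cavity unpressurized), the state closest to the living organ.

Torsion analysis regresses the signed per-element azimuth change about X
(positive anticlockwise viewed from +X) on element height, with a 99%
confidence band on the slope and mean-prediction bands; per-cell tilt
change is the signed rotation of each cell's long axis.  The helical
specimens torque anticlockwise during cell inflation and clockwise during
cavity inflation with the distortion accumulating over height, while
untilted specimens show slopes 20–50× smaller — the pattern observed in
twisted versus non-twisting fossil capsules.

## Morphospace and fitness landscape

The seven attributes (mean cell volume, its CV, anisotropy, twist, cavity
volume, sphericity, flatness) feed a centered PCA — unscaled by default,
matching the reference statistical environment's defaults, with a
`scale_pca` switch since the units are heterogeneous.  Clustering (k-means
with 100 seeded restarts, exact build+swap PAM, UPGMA average linkage cut
at height 3) always uses z-scored attributes: on raw units the μm³ volume
column dominates every Euclidean distance and a cut height of 3 is
meaningless.  On a 15-specimen synthetic cohort (5 seeds × 3 morphotypes)
all three methods recover the generator labels exactly with mean
silhouettes ≈ 0.8.

The fitness landscape normalizes three dispersal attributes to [0, 1] by
min–max (spore yield ∝ cavity volume; rupture pressure ∝ ejection force;
stress-assisted score ∝ release success) and scores
f = sqrt((a₁² + a₂² + a₃²)/3), so the all-ones corner scores exactly 1.
Niche regions: within 0.3 of either corner (near-min / near-max, max
taking precedence), within 0.2 of the cube centre (generalist), otherwise
specialist; the three spheres are geometrically disjoint.

## What the synthetic data do and do not show

The generator emulates the morphotypes' shapes, fourfold symmetry, tilted
cell files, cell-size jitter and wall depth, but not real cell topology
(neighbour-count statistics of fossil epidermis are not modelled — the
grid-plus-jitter pattern is an assumption), taphonomic deformation,
material heterogeneity, or epidermal thickness variation.  Passing tests
therefore demonstrate that the pipeline recovers known inputs and
reproduces the qualitative mechanical signatures on idealized shells; they
do not certify quantitative agreement with any particular fossil
reconstruction.  Two desk-scale limits are worth naming: the linearized
rupture benchmark is unreachable by any finite-strain model (see above),
and on the fusiform preset the turgid cell-bulge peaks exceed the
dried-state organ-level concentration, so the "drying raises the highest
stress" signature, robust for the spherical shells, can invert for
fusiform ones at these cell counts.

## Problem sizes and determinism

Specimen meshes run at (3–6) × 10³ elements, sweeps at 0.45–1.0 MPa in
0.01 MPa steps with warm starts; a full specimen analysis (inflation,
sweep, rupture, drying) takes tens of seconds on one core.  All
randomness flows from per-spec integer seeds through NumPy generators;
rebuilding a spec is bit-reproducible, k-means restarts are seeded, and
reruns of the pipeline produce byte-identical CSV outputs.
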