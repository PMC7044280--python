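# Methods

This note documents the model behind `carpofem`: what is simulated, the
choices made where the design was genuinely open, and what the synthetic
geometry can and cannot say about real carpal bones.

## Problem

The os centrale is fused to the scaphoid in African apes and humans. If
that fusion is a mechanical adaptation, a fused scaphoid-centrale should
carry lower stress than a virtually separated one under knuckle-walking
loads. The package frames this as a controlled in-silico contrast: two
assemblies that are *identical in every element* except that in one the
scaphoid-centrale interface is a continuous solid and in the other it is
a frictionless non-separating joint plus an inter-bone ligament.

## Synthetic geometry

Real study geometries would be CT-derived bone surfaces; here they are
replaced by parametric stand-ins designed to preserve the *load-path
topology* of the wrist rather than anatomical shape:

* Three convex bodies carved from one shared cubic lattice (pitch =
  target edge length, default 1 mm) and split into tetrahedra with a
  consistent Kuhn (6-tet) subdivision. Carving all bodies from the same
  lattice makes opposing contact patches mirror-conforming — every
  contact node has an exactly coincident partner — so non-separation
  contact reduces to exact linear node-pair constraints and the whole
  problem stays linear.
* Default proportions follow carpal anatomy at a human scale: capitate
  semi-axes (7, 6, 10) mm (the largest bone, its column runs the full
  proximodistal height), scaphoid (5, 4, 6) mm resting obliquely against
  it, centrale (3.5, 3.5, 3) mm — a small flat bone wedged between
  scaphoid and capitate, reaching the distal (trapezoid) support.
* The assembly is passed through one global smooth deformation: a gentle
  barrel profile, a seeded low-frequency perturbation field (amplitude
  0.25 mm, wavelengths ≥ 12 cells) that gives each seed an individual
  "bone surface", and a uniform shear that tilts every articular plane
  30° to the load axis. Because a single map is applied to every body,
  contact pairs remain exactly coincident and no element inverts.
* The perturbation is tapered to zero within three cells of the
  articular interface planes. Articular surfaces are smooth
  (cartilage-covered) in life; roughening a contact plane would make the
  tie normals non-uniform and spuriously interlock a joint that the
  model treats as freely sliding.
* The 30° articular obliquity matters mechanically, not cosmetically:
  a joint plane perpendicular to the load transmits a compressive load
  for free even when sliding is frictionless, and fusing it changes
  nothing. Carpal articulations are oblique to the load axis (the
  scaphoid famously lies 30–45° to the wrist's long axis), and it is
  exactly this obliquity that gives the fusion its job — carrying shear
  across the scaphoid-centrale interface. 30° was fixed as the
  anatomical default together with the bone proportions.
* The fused variant merges scaphoid + centrale into one body (shared
  lattice nodes, interface removed); its volume is exactly the sum of
  the parts. The unfused variant is therefore a literal "virtual cut" of
  the fused bone.
* Species differ by load, by an isometric size factor
  (mass / 72.1 kg)^(1/3) on all coordinates, and by their perturbation
  sub-seed (`(master·1000003 + species_index) mod 2^31`). Real
  inter-specific shape differences are out of scope.

Surface triangles carry exactly one region label: loaded facets (radial
on the scaphoid, lunate on the capitate — the lunate facet covers 60% of
the capitate's proximal face), fixed distal facets, three lateral
restraint patches, ligament attachment patches, the three contact
patches, and free surface.

## Mechanical model

* **Units** mm / N / MPa (10 GPa stored as 10000 MPa); g = 9.80665 m/s²
  (the tabulated species loads round-trip to 0.01 N only with the
  standard constant, not the rounded 9.81).
* **Elements.** Cancellous bone: constant-strain tetrahedra. Cortical
  bone and cartilage: constant-strain plane-stress membranes on every
  surface triangle. The membranes share the solid's surface nodes, which
  realises total DOF coupling without extra constraint machinery; they
  carry no bending stiffness. This is a deliberate reduction of a full
  shell formulation — both layers are thin and continuously bonded to
  the substrate, and the fused/unfused contrast compares two models with
  identical layer treatment — but absolute shell bending effects are not
  represented.
* **Cortical thickness** defaults to 1.0 mm per bone (configurable per
  bone); cartilage thickness 0.55 mm everywhere, as a conservative
  constant for hominoid wrist cartilage. The cartilage layer covers the
  whole bone surface, an intentional simplification; cartilage elements
  are excluded from the per-bone stress statistics.
* **Ligaments.** Total rigidity 40 N/mm realised as 8 parallel strands
  (count configurable). Unfused: each strand is two serial segments
  scaphoid→centrale→capitate of 2·(40/n) N/mm each, so the strand's
  series value is 40/n and the parallel aggregate is exactly 40 N/mm.
  Fused: n direct scaphoid→capitate strands of 40/n. Attachment nodes
  are picked deterministically, spread over the attachment patches.
* **Lateral restraints.** 20.5 N/mm per restraint region (lunate,
  hamate, trapezoid), interpreted per-region rather than as a global
  total, applied as grounded springs along the local surface normal and
  partitioned by tributary area (sum exact to 1e-9 relative).
* **Contact.** Per coincident pair, (u_A − u_B)·n = 0 with n the
  undeformed outward normal of the scaphoid-side body, held constant
  (small-displacement linear statics). Implemented by exact Gaussian
  elimination of the constraint rows (nodes lying on two patches couple
  their rows, so single-pass master-slave substitution is insufficient);
  the reduced system stays SPD and is solved by sparse LU. Tangential
  sliding is genuinely free: the tests assert both zero normal gap
  (≤ 1e-10 mm) and nonzero slip in the loaded models.
* **Loads.** F = fraction · m · g (fraction 0.2), applied along the
  proximodistal axis, optionally tilted (default tilt axis: y) by 5°;
  split radial : lunate in proportion to facet area by default (the
  split is configurable because the true partition is unknown); lumped
  area-consistently so the resultant equals F·direction to round-off.

## Stress statistics

Per-element constitutive stress (constant per element), von Mises
reduction, then per bone (cancellous + cortical, cartilage excluded):

* MWAM = Σvᵢwᵢ/Σwᵢ and MWM / weighted quartiles by the smallest-value
  cumulative-weight rule, with wᵢ = element volume (tets) or
  area × thickness (membranes). These weight-by-size statistics are the
  appropriate summaries on a quasi-ideal mesh, where element sizes are
  nearly but not exactly uniform (the generated meshes have a volume CV
  of a few percent).
* Box-plot summaries use min/max whiskers and weighted quartiles; the
  weighted (rather than unweighted) quartile convention was chosen for
  internal consistency with MWM.

## Inference

Per bone and angle, the five fused and five unfused species MWAMs are
compared with Welch's two-sample t-test (two-sided; fused minus unfused,
so t < 0 means the fusion lowers stress), preceded by a Shapiro-Wilk
check on the pooled n = 10 sample. Shapiro-Wilk is implemented directly
from Royston's approximation (normal scores (i−3/8)/(n+1/4), polynomial
corrections to the two extreme weights, log-normal / logistic-normal
p-value transforms, exact √½ weight at n = 3) in full double precision;
scipy's compiled routine serves as an independent cross-check in the
tests (agreement ~1e-6, limited by its internal quantile kernel).
The 5° tilt sensitivity set compares pooled MWAM samples across angles
(n = 10 vs 10 per bone).

## Numerical choices

* Direct sparse LU (`scipy.sparse.linalg.splu`) with a relative residual
  guard of 1e-8; singular reduced operators (unsupported rigid modes)
  raise instead of returning garbage.
* Equilibrium is checked on every solve: applied loads + fixed-support
  reactions + foundation-spring reactions balance to ≤ 1e-8 relative.
* Tie pairs whose scaphoid-side node is fixed are swapped (or dropped
  when both sides are fixed and the tie is vacuous) so a DOF is never
  simultaneously fixed and a constraint pivot.
* Weighted quantiles break ties by stable sort; the cumulative-weight
  comparison uses a 1e-12 relative guard so exact-half boundaries are
  deterministic.
* Default problem sizes: ~27k tetrahedra + ~9k membranes per model
  (1 mm lattice), ~17k DOFs — about a second to assemble and a few
  seconds to solve; the full 20-model study runs in about a minute.
  The cantilever verification uses a 60×12×12 mesh, the documented
  refinement at which the tip deflection is within 5% of P·L³/(3EI).

## What the synthetic data can and cannot show

The generator emulates the *structure* of the study — multi-body carpal
load transfer with fused/unfused variants, species-scaled loads,
size-weighted stress summaries — not real carpal anatomy. Passing tests
demonstrate that the pipeline reproduces the qualitative mechanical
findings (fused scaphoid-centrale < unfused scaphoid MWAM in every
species; centrale highest, capitate lowest among unfused bodies;
orderings unchanged at 5°) on geometry whose proportions and joint
obliquity are anatomically motivated. They do not validate absolute
stress magnitudes, species-specific shape effects, or the published
t statistics, all of which depend on CT-derived geometry this package
deliberately does not use. With five synthetic replicates the Welch
t-values are small; the robust output is the sign and the per-species
ordering, not significance.

## Known limitations

* Membrane (not bending) shells; homogeneous isotropic tissues; no
  muscle/tendon forces; no friction; geometric linearity throughout.
* Contact normals are fixed at their undeformed directions.
* The scaphoid-centrale "joint space" defaults to zero gap (the
  cartilage layer is represented by membranes, not by a geometric gap);
  a nonzero `cartilage_gap` offsets the bodies but keeps the tie
  kinematics.
* One ligament system only (the scapho-centrale-capitate chain); other
  carpal ligaments are subsumed into the lateral elastic restraints.
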