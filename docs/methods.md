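# Methods

## The question the model answers

Grass (dumbbell-shaped) guard cells can be symplastically connected
through gaps in the shared ventral wall, which would let the pair
equalise turgor and act as a single osmotic unit; kidney-shaped guard
cells of most other plants are typically isolated. `stomamech` asks what
pressure equalisation buys mechanically: pressurised, anisotropic
thin-walled guard-cell complexes are relaxed to mechanical equilibrium
across a grid of asymmetric pressure splits, and pore aperture and wall
stress are compared between the equal (0.5:0.5) scenario — equivalent to
a connected pair — and unequal scenarios representing isolated cells.

## Mechanical model

Walls are constant-strain triangular membrane elements (no bending
stiffness, plane stress) with per-element thickness, carrying a
transverse isotropic Saint–Venant Kirchhoff material: second
Piola–Kirchhoff stress S = C : E, with E the Green–Lagrange strain
expressed in an orthonormal element frame whose first axis is the local
cellulose microfibril direction. The plane-stress stiffness is built
from a fibre modulus E2, a transverse modulus E1 (= E3) and a single
Poisson-like parameter ν, symmetrised through ν21 = ν·E1/E2; the shear
entry uses G = √(E1·E2)/(2(1+ν)), which reduces to the isotropic shear
modulus when E1 = E2. The law is linear in E and objective under large
rotations, appropriate for thin pressurised walls at moderate strain.

Turgor is a follower load: each triangle contributes
p_net × (deformed area) × (deformed normal), split equally over its
vertices and recomputed every iteration. Shared walls (triangles listed
by two cells) feel the pressure *difference* across the wall — this is
what makes asymmetric splits deform the ventral wall between the guard
cells. Reported stress is the in-plane Cauchy tensor
σ = F S Fᵀ / J (J the in-plane area ratio, out-of-plane component zero
under plane stress); its trace equals the sum of the two in-plane
eigenvalues. The scalar summary per state is the mean of the largest
⌈0.1 N⌉ element traces, by element count, unweighted by area, strict
count after a stable sort.

Equilibrium is found by pseudo time-stepping (dynamic relaxation):
vertices carry fictitious masses proportional to a local stiffness
estimate, positions advance explicitly under elastic plus pressure
forces, and the iteration stops when the RMS residual on free vertices
falls below `tol_rel` (default 1e-4) times the mean pressure-force
magnitude. Damping is primarily *kinetic* (velocities are zeroed at
kinetic-energy peaks) with a small mass-proportional viscous term
(default 0.02 per unit pseudo-time); on these meshes kinetic damping
converges an order of magnitude faster than purely viscous damping at
any coefficient we tried, which is why it is the default. Loads ramp
linearly over `ramp_steps` (default 400) iterations when starting from
the reference state; warm starts skip the ramp. The solver is fully
deterministic: fixed assembly order, no randomness, bit-identical
reruns. A numba-compiled fused force kernel accelerates assembly; the
pure-numpy path computes the same numbers (asserted in the tests) and is
used automatically if numba is absent.

## Synthetic geometry: what it emulates, and what it does not

The study that motivates this package ran on confocal-derived meshes of
real barley and onion stomata; those segmentations are not part of this
artifact. The generator replaces them with parametric idealisations
that keep the features the mechanics depends on:

* **Dumbbell (grass) complex** — each guard cell is a swept capsule: a
  central rod (circular lumen, radius 1.4 μm) whose wall is 3× thicker
  than elsewhere, joining two thin-walled bulbous ends (radius 7 μm).
  The two cells share a flat ventral wall disc (radius 4.5 μm) at each
  bulbous end, meshed once with both cells registered on it. Fibres are
  longitudinal. Lens-shaped subsidiary cells close over the dorsal
  strips of the guard cells (sharing those walls) and are fixed over
  their outer lateral patch — the only kinematic boundary, matching the
  observation that grass complexes do not widen. The initial pore is a
  slightly open slit (half-width 0.25 μm) so the rim and its normals are
  well defined; complex length ≈ 45 μm.
* **Kidney (onion) pair** — each guard cell is a circular tube
  (radius 4.5 μm, uniform 0.6 μm wall) swept along half of an ellipse
  around an elliptical pore (semi-axes 8 × 1.5 μm), capped and fixed at
  the two polar junctions. Fibres are circumferential (hoop), so
  pressure extends the cell lengthwise and bows the arc outward — the
  classical kidney opening mechanism. Complex length ≈ 34 μm.

Within-pair size dimorphism is realised by scaling GC1's bulb/tube radii
up and GC2's down, with the scale found by root bisection until the
fractional volume difference matches the target (default targets 9%
grass, 6% onion; tolerance 0.1% of the target). Replicates for
statistics jitter radii and thicknesses by ±5% from a seeded stream; an
optional smooth surface-jitter field (off by default) roughens the
walls without breaking shared-wall watertightness.

Parameter defaults the source imagery does not constrain were chosen
once, during model development, to put the synthetic complexes in the
mechanically sensible regime: wall moduli (barley GC E2 = 600,
E1 = 150 MPa longitudinal-stiff; onion GC E2 = 600, E1 = 100 MPa
hoop-stiff; subsidiary cells isotropic 150 MPa) keep peak wall strains
below ~0.4 across the 2–9 MPa grid; the fixed subsidiary-cell pressure
(1.2 MPa) slightly exceeds the per-cell guard pressure of the lowest
total, so subsidiary backpressure dominates exactly where guard turgor
is weakest. That antagonism is what produces the grass model's
low-pressure asymmetry penalty: a guard cell whose turgor falls below
subsidiary pressure is squeezed shut on its side of the pore, while at
high totals both cells out-press the subsidiaries and the penalty
fades. With these defaults the dumbbell model at 2 MPa total opens to
only ~83% of its equal-split maximum under a 0.3:0.7 split, whereas the
kidney model — whose cells are mechanically decoupled apart from their
shared anchoring — stays above ~98% everywhere on the grid.

What passing tests therefore show is that the *mechanisms* (shared-wall
coupling, subsidiary antagonism, anisotropy-directed inflation) produce
the study's qualitative behaviour on an idealised geometry; they do not
certify absolute pore areas or stress magnitudes for real stomata,
which depend on the real cell shapes and the unpublished material
table: the synthetic complexes' absolute stress summaries differ from
mesh-specific reference values by factors of a few, while reproducing
the orderings and sweep shapes.

## Read-outs

* **Pore area**: shoelace area of the ordered rim loop projected onto
  the epidermal (XY) plane, orientation-independent; a self-intersecting
  projection (which occurs when the weak-side crest is pushed across the
  mid-plane at extreme splits — the model has no contact mechanics)
  falls back to the signed-area magnitude with a warning. A best-fit
  plane option exists for tilted imported meshes. For the kidney pair
  the rim excludes the near-polar arc where the idealised tubes
  approach the mid-plane.
* **Cell volume / surface area**: divergence-theorem volume over each
  cell's closed outward-oriented surface; within-pair contrasts use
  100·|v1 − v2| / mean(v1, v2) (pair-mean denominator; the larger-value
  denominator is a documented alternative).
* **Normalised aperture**: pore area divided by the per-total-pressure
  maximum over the ratio grid, converged solves only.

## Sweeps and statistics

The default grid crosses totals 2–9 MPa (1 MPa steps) with GC1 shares
0.1–0.9 (0.1 steps). Cases are solved low-pressure-first, fanning out
from the balanced split, each warm-started from the nearest solved
neighbour in (T, r); spot re-solves from rest agree within solver
tolerance. Non-converged cases are excluded from normalisation and the
sweep aborts if more than 20% fail.

Scenario stress comparisons use classical one-way ANOVA (unbalanced
decomposition where needed) with Tukey HSD at α = 0.05 and a compact
letter display built by insert-and-absorb; groups sharing a letter
cannot be distinguished. The pipeline reports its own degrees of
freedom. Within-pair geometry uses a Shapiro–Wilk gate (α = 0.05) on
pair differences to choose between the paired t-test and the Wilcoxon
matched-pairs signed-rank test; all-zero differences are reported as
degenerate with p = 1. No multiple-testing correction is applied beyond
Tukey HSD.

## Numerical choices and problem sizes

Units are μm–MPa–μN throughout. Default meshes resolve to ~4,900
triangles (dumbbell complex, target edge 1.6 μm) and ~2,000 (kidney
pair, 1.3 μm); halving the target edge changes cell volumes by < 2%.
At these sizes a cold equilibrium solve takes seconds and the full
72-case kidney grid runs in well under a minute on one CPU, which is
the scale at which the acceptance checks and the analysis drivers run.
Degenerate elements (area < 1e-12 μm²) raise immediately; NaNs abort
with the iteration index; non-convergence is returned as a flagged
state, never silently.

## Known limitations

No contact mechanics (walls may interpenetrate at extreme splits), no
bending stiffness (fine for thin walls, wrong for thick-plate effects),
no viscoelasticity, growth or wall remodelling, and no explicit fluid
exchange through the wall gaps — the 0.5:0.5 load case *is* the
gap/connected scenario, as in the source framework. The subsidiary
cells are mechanical bladders with fixed turgor, not osmotically active
cells. Absolute apertures and stresses are idealisation-dependent;
within-grid normalised comparisons are the intended use.
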