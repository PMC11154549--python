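# Methods

This note documents the models, conventions and numerical choices behind
`crystalhabit`, and what the synthetic-data tests do and do not establish
about real molecular-dynamics output.

## Lattice arithmetic

Unit cells are handled in the general triclinic case through the metric
tensor, even though the bundled ISMN cell is tetragonal; the cost is
negligible and it removes a silent restriction.  The Cartesian frame places
**a** along x and **b** in the x–y plane (right-handed, **c*** along z for
orthogonal cells).  d_hkl = 1/|G(hkl)| with G the reciprocal-lattice
vector; plane normals are G's direction.  Cell validation rejects angle
triples that violate the triangle-type inequality (negative metric
determinant).

Face forms are orbits under proper-rotation point groups ("1", "2", "4",
"222", "422", as integer matrices closed into groups).  The ISMN structure
(space group P4₃) uses group "4", the pure rotations about c.  This is
deliberate: the non-centrosymmetric group keeps (h k l) and (h k −l) as
distinct multiplicity-4 forms, which is what the tabulated six forms
require.  Laue-class expansion would merge them.

## Growth morphology

The habit is the intersection of half-spaces { r · n(hkl) ≤ s·|E(hkl)| }
over all equivalents of all forms.  The global scale s (default 1) is
physically meaningless — only proportionality is defined — so vertex
coordinates carry the energy unit as a pseudo-length and every reported
quantity (area fractions, aspect ratio, relative surface/volume) is
scale-free.  Absolute facet areas are therefore *not* comparable to areas
printed for any particular rendering of the same habit; fractions are.

Implementation: boundedness is established first by linear programming
(searching for a recession direction u with n·u ≤ 0 for all planes; an
"open morphology" error names the uncovered direction), then
`scipy.spatial.HalfspaceIntersection` about the origin — interior by
construction since all distances are positive — followed by vertex
deduplication at tolerance 1e-8·(max distance) and facet grouping by
plane membership at the same tolerance.  Facet polygons are ordered by
angle in the facet plane; the polyhedron volume is the facet-pyramid sum
Σ A_i d_i / 3, cross-checked in tests against rejection-sampled Monte
Carlo volume.

**Morphological importance.**  Rounded tabulated energies can leave a
numerically tiny sliver facet (~10⁻³ % of the surface) on a form that an
exact construction would just eliminate — the solvated ISMN habit does
exactly this on (1 1 −1).  Reports therefore classify a form as *present*
when it carries at least 0.1 % of the surface area (configurable);
the geometric facet list itself is untouched.

**Aspect ratio** is the max/min extent of the habit along the Cartesian
axes of the crystal frame.  This reproduces the intuitive scores (cube 1,
2×1×1 box 2) and the reference needle value 3.944, and is the natural
needle/plate classifier when the elongation axis is a crystal axis, as
here.  A caliper-width definition over facet normals and vertex directions
was considered and rejected: it scores a cube at √3.  For the solvated
habit the axis convention gives 3.69 (reference prints 3.886, definition
unstated); the qualitative statement — elongation decreases on solvation —
is robust to the convention.

**Relative surface-to-volume** is sphericity-normalised: surface area over
the area of the equal-volume sphere (1 for a sphere, ≈1.2407 for a cube).
This convention reproduces both tabulated ISMN values (1.343 vacuum, 1.315
solvated) to three figures, which supports it being the convention used.

## Attachment-energy arithmetic

E_int = E_tot − (E_cry + E_sol); E_s = (Z_cry/Z_hkl)(A_hkl/A_box)·E_int;
E′_att = E_att − E_s.  Units are fixed (kcal/mol and kcal/mol/unit cell);
no unit inference is attempted because the conversion factor exists
precisely to reconcile the two.  Interaction energies may be supplied as
per-face scalars (as in the bundled tables) or as per-frame component
series averaged over a trailing window (default: last 100 stored frames).
Growth-rate ranking orders faces by descending |energy| (fastest first);
ties are kept in input order and flagged.  Box-sizing validation checks
lateral lengths ≥ 2·d_c, slab thickness ≥ d_c, vacuum pad ≥ 100 Å and
consistency of the declared A_hkl/A_box with the replica counts — reported
as named violations, not exceptions, since a spec check is a diagnostic.

## Trajectory estimators

Trajectories are ordered frames of labelled coordinates in an orthorhombic
box, periodic in x/y by default (slab geometry with a z vacuum pad) or in
all three axes for synthetic bulk systems.

**RDF.**  g(r) = ⟨shell count / shell volume⟩ / (N_counted / V_box),
averaged over frames and reference atoms, minimum image along periodic
axes, self-pairs excluded.  The normalising density is the *whole-box*
average — including any vacuum — so peak heights are comparable across
face systems sharing a box construction, but not to bulk-normalised RDFs
from other software.  Default bin width 0.05 Å resolves peak positions in
the 2.3–2.5 Å hydrogen-bond window.  r_max must not exceed half the
smallest periodic box length.  Peak classification: < 3.1 Å hydrogen bond,
3.1–5 Å van der Waals, beyond 5 Å unassigned.

**MSD / diffusion.**  Multiple-time-origin MSD via the FFT autocorrelation
identity (O(F log F) per particle), averaged over selected atoms;
D = slope/6 from least squares on a lag window, reported in 10⁻⁸ m²/s
(numerically identical to Å²/ps, asserted in code).  The default window is
2–20 % of the maximum lag: at long lags the origin-averaged MSD has few,
strongly correlated samples, and fitting there inflates the variance of D
without improving its bias — measured on 500-walker × 2000-frame Brownian
data, the 10–50 % window gives ~3 % realization scatter with single-run
errors up to ~9 %, the 2–20 % window ~1.7 % scatter.  The reported
standard error is the ordinary fit s.e. and understates realization error
on smooth origin-averaged curves; recovery accuracy is what the tests
certify.  Wrapped input is unwrapped by accumulating minimum-image
frame-to-frame displacements (valid while per-frame moves stay below half
a box length); generators store exact unwrapped coordinates alongside.

**Density profiles.**  Per-bin counts along an axis normalised by the
species' mean density over the analysis region, so a uniform species
profiles at 1 ("relative concentration"); default bin 1 Å; optionally only
the trailing window (e.g. last 200 ps) of the trajectory is analysed.

## Hydrogen bonds

Geometric criterion: H···A ≤ 3.1 Å (the RDF hydrogen-bond window) and
D–H···A ≥ 120°.  The angle cutoff is a package default — reference angle
distributions start near 120° — and is configurable.  "Bond length" is the
H···A distance, consistent with 2.3–2.5 Å peaks being read as hydrogen
bonds (D···A would sit near 3.4 Å).  One hydrogen may bond several
acceptors; each qualifying (H, A) pair is one record.  The census reports
mean length/angle, S₁ (% of bonds shorter than 2.5 Å), S₂ (% with angle
above 150°), N_HB (mean bonds per frame), N_H1 (distinct donor hydrogens
bonded anywhere in the window), N_HB/N_H1, N_HB/A_box, and
(N_HB/A_box)·A_hkl — the per-unit-cell-face count that links the census to
the E_s conversion.  Ratios with empty denominators are NaN and flagged,
never silently zero.  Length/angle probability densities use 0.02 Å / 2°
bins; band probabilities integrate partial bins exactly.

## Accessible surface area and rugosity

Shrake–Rupley sampling on a deterministic Fibonacci sphere lattice (no
RNG; results are bit-stable and translation-invariant; rotation changes
results only at sampling resolution, ~0.5 % at 1000 points).  Default
probe 1.4 Å (water-sized; the reference tool's probe is unstated, so
tabulated S values are validated as quotients of the printed areas, not as
SASA regressions).  Slab rugosity counts only the accessible area of atoms
within a configurable depth of the top surface, with 3×3 lateral periodic
images suppressing edge artifacts.  Van der Waals radii are Bondi values.

## Synthetic generators

All generators draw from `numpy.random.default_rng` (PCG64) so a fixed
seed reproduces output byte-for-byte; parameters are echoed into trajectory
metadata and survive the XYZ round trip.  They emulate the *statistical*
features the estimators measure — known diffusion coefficient, known
z-density, known bond-geometry distributions, uniform ideal gas — and
none of the physics of a real solvated slab: no excluded volume, no
intermolecular correlations, no force field.  Passing recovery tests
therefore certifies the estimators (given correctly labelled, correctly
boxed input they return the right numbers), not the realism of any MD
engine upstream.

Brownian walkers use independent Gaussian steps of per-axis variance
2·D·dt.  Layered boxes sample z from arbitrary densities by numeric
inverse-CDF (4096-point trapezoid grid).  Hydrogen-bond scenes place
triples on a 9 Å grid (so neighbouring triples cannot create accidental
bonds under the 3.1 Å cutoff) with lengths/angles from clipped Gaussians
inside the acceptance windows; each decoy violates exactly one criterion.
Model slabs are simple cubic — sufficient for surface-bookkeeping tests,
not a molecular surface.

## Pipeline and formats

The YAML-driven pipeline runs vacuum habit → per-system MAE table →
solvated habit → any configured estimators, writing CSV/JSON and OFF/OBJ
meshes plus a manifest with the package version, seed and a SHA-256 hash
over the config and all referenced inputs (reruns on identical inputs are
bit-identical up to timestamps).  Stage failures halt with the stage name.
Trailing analysis windows accept either picoseconds or frame counts, since
both conventions appear in practice.  The multi-frame XYZ dialect stores
the box (and generator metadata) on the comment line; PDB I/O (CRYST1 +
MODEL frames) goes through biotite, CIF cell blocks through gemmi.

## Problem sizes

Statistical tests are sized so that their tolerances sit ≥3σ from the
expected estimator scatter: ideal-gas flatness at 800 atoms × 300 frames
(±0.02 per bin), diffusion recovery at 500 walkers × 2000 frames (±5 %),
Monte-Carlo volume checks at 10⁶ samples (±1 %).

## Known limitations

Attachment and interaction energies are *inputs*: no lattice sums or force
fields.  Boxes are orthorhombic; RDF minimum image assumes that.  The MSD
assumes isotropic diffusion (scalar D).  SASA is the accessible surface,
not the molecular (Connolly) surface.  Equilibrium (γ-based Wulff) and
BFDH morphologies are not produced, though BFDH distances are trivially
available from d_hkl.
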