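# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinate models and selections

Atomic models are held as ordered lists of atom sites keyed by
`(chain, residue number, insertion code, atom name)`. Author residue
numbering is authoritative and never renumbered: every domain anchor used
in this package — the Mfd relay helix (548–577), the TD1 superposition
core (580–780), the nucleotide-responsive N-portion of TD2 (781–939) — is
an author number of the 1148-residue *E. coli* Mfd sequence, and silently
renumbering would corrupt them. Alternate locations collapse to the
highest-occupancy conformer (ties: first encountered); a residue is never
duplicated, matching single-conformer analysis.

Selections name a chain *role* (Mfd, RNAP_beta, RNAP_betaprime, t_strand,
nt_strand, RNA), resolved per state through an explicit chain map in the
ensemble manifest. Roles are never guessed from chain letters because
depositions differ in chain naming. Missing residues inside a selected
range are dropped but counted (coverage report), never interpolated.

The default domain registry is an editable YAML document. Boundaries fixed
by the structural annotation of Mfd carry provenance `structure anchor`;
all others — notably the RNAP clamp, βprotrusion and βlobe-Si1 module
limits, for which no single canonical residue-range definition exists —
are `package default` and are expected to be overridden per study. Every
motion result records the provenance of the anchor it used, so a reader
can tell which numbers rest on package-chosen boundaries.

## Superposition

`kabsch` computes the optimal proper rotation by SVD of the weighted
covariance matrix; a determinant-−1 solution is corrected by flipping the
smallest singular direction, so reflections are never returned. Inputs
with fewer than three pairs, or whose second singular value is ~0
(collinear points), raise a degenerate-configuration error rather than
returning an arbitrary axis.

`iterative_align` emulates the outlier-rejecting protocol commonly used to
compare conformational states: fit, drop pairs with deviation
> `reject_factor × rmsd`, refit, for up to `cycles` rounds, stopping when
nothing is dropped or fewer than three pairs would remain. Defaults are
`cycles = 5`, `reject_factor = 2.0`; both are exposed because published
protocols name the tool rather than the parameters. The rejection
threshold has a 10⁻⁶ Å floor so that an exact fit (rmsd ≈ machine epsilon)
does not reject everything. Two RMSD values are carried everywhere:
`rmsd_kept` over the retained pairs and `rmsd_all` over the original full
pairing under the final transform, because published tables report either
convention and the two differ meaningfully once rejection is active.

Pairwise matrices average the i→j and j→i fits (rejection makes the two
directions differ slightly); the maximum asymmetry seen before averaging
is recorded on the matrix. Matrix entries are symmetric and non-negative;
the triangle inequality is *not* asserted — outlier rejection breaks
metricity by construction.

## Domain motion

The procedure is fixed: (1) anchor state B onto state A by
`iterative_align` over the anchor selection; (2) Kabsch-fit the domain's
paired Cα between the anchored placements; (3) angle =
`arccos((tr R − 1)/2)`, axis from the antisymmetric part of R — near 180°
the antisymmetric part vanishes, so the axis is taken from the
+1-eigenvector with a deterministic sign (largest-magnitude component
positive); (4) screw point = the point on the axis minimizing the
translation norm, from the least-squares solution of `(I − R)p = t⊥`;
(5) COM displacement between domain Cα centroids (uniform mass — the
analyses are Cα-based throughout), with its signed projection on an
optional reference axis. The downstream direction (positive projection) is
set by the caller's axis orientation, by convention from the upstream DNA
end toward the RNAP active site.

Angles are reported in [0°, 180°]. A corkscrew walk of more than half a
turn around the DNA (e.g. a ~260° winding) produces the same rotation
matrix as its 360°-complement; a single matrix cannot distinguish them.
Rather than invent an unobservable sign, the descriptor reports the
[0, 180°] angle plus a winding sense (sign of the rotation axis projected
on the reference axis) from which the handed interpretation can be
reconstructed when the trajectory is known to exceed 180°.

Invariants verified by the test suite: conjugation invariance under a
global rigid transform of both states; composition consistency
(R(A→C) = R(B→C)·R(A→B) on noiseless data, residual < 0.01°);
angle(R) = angle(Rᵀ).

## Pathway ordering

The anchor state is the ensemble member with the smallest full-pairing
RMSD to an external reference model (for the motivating system: the
crystallographic apo conformation of the free factor); a tie within
10⁻⁶ Å is an error demanding an explicit choice. Ordering is by exhaustive
enumeration of all (n−1)! open paths from the anchor — exact by
construction, feasible for n ≤ 12, and refused above that rather than
silently switching to a heuristic. Ties break lexicographically on the
label sequence, so the result is independent of input order. The default
matrix mode for pathway work is `all` (full-pairing RMSD), since the
ordering concerns whole-complex similarity; a `closed` option charges the
return leg for cyclic processes (the hydrolysis cycle C1→…→C5→C1) but is
not the default, matching the open loading-to-cycle construction.

The loading-vs-cycle partition cuts the single-linkage dendrogram at its
final merge into exactly two groups and reports within-group max and
between-group min distances; if the separation does not exceed the spread
("no gap", e.g. all states equidistant), it raises instead of returning an
arbitrary split.

## DNA geometry

Registers use transcription coordinates: +1 at the template base in the
active site, negative upstream, stored in the manifest's register map —
matching footprint language like "−34 to −14". Base-pair frames take the
midpoint of paired C1′ atoms; the local axis at pair *i* is the unit
secant from midpoint(i−w) to midpoint(i+w), w = 2 by default (one-sided at
the ends). The 5-bp window suppresses single-step noise at the cost of
smearing sharp kinks across ~2w steps; w is exposed as a parameter. The
global bend is the angle between the first and last local axes. The kink
is the largest consecutive-axis angle and its register; for a single sharp
kink the *bend* recovers the planted kink angle exactly while the
consecutive-axis profile (which spreads the turn over the window) serves
to localize the register to ±1.

Minor-groove widths use the short-diagonal convention: width(i) = min over
cross-strand offsets +2…+5 of the P(t, i)–P(nt, i+k) distance, minus 5.8 Å
for two phosphate van-der-Waals radii. Offsets and the subtraction
constant are configurable. Absolute calibration is by the package's own
ideal-fiber baseline (5.79 Å for the generator's geometry); registers with
missing phosphates are reported as undefined, never interpolated.

Contact classes are distance-only, deliberately: hydrogen bond ≤ 3.5 Å
between N/O atoms, ionic ≤ 4.5 Å between a charged side-chain group and a
phosphate oxygen, generic van der Waals ≤ 4.0 Å; a contact takes the
tightest class it satisfies. No angular criteria are applied — at the
3–4 Å resolutions typical of the motivating data, donor-hydrogen geometry
is not reliably modeled, and distance-only definitions are what the
field's contact tables use. Footprint shifts are differences of
contact-weighted mean registers, reported both fractionally and rounded.

## Interface areas

SASA is Shrake–Rupley style: 960 golden-spiral points per atom on the
solvent-expanded sphere (probe 1.4 Å), occlusion tested against all
neighbors within reach via a k-d tree. Radii: C 1.7, N 1.55, O 1.52,
P 1.8, S 1.8 Å; unknown elements fall back to 1.8 Å with a warning (or
raise, if fallback is disabled). Hydrogens are ignored (heavy-atom
models). The interface area is `(SASA_A + SASA_B − SASA_AB)/2`, computed
on the A∪B atoms in isolation by default (a `context` argument includes
surrounding atoms). This is a generic buried-SASA measure — it
approximates, but does not reproduce, any specific interface server's
algorithm (those exclude particular atom classes); comparisons against
published interface areas should allow ~15%. Numerical floor: values in
(−0.5, 0) Å² are clamped to zero with a warning; anything lower raises.

## Scaffold sequences

Hybrid length is the longest contiguous Watson–Crick run pairing the RNA
3′ terminus against any position of the template strand, antiparallel,
scanning all offsets and reporting ties. Pairing is strict Watson–Crick
(A·T, A·U, G·C); G·U wobbles are excluded so that "n base pairs" means
canonical pairs. Segmentation compares top[i] with bottom[n−1−i] at fixed
antiparallel register with no indels — scaffold oligos are designed
register-aligned — labeling maximal runs duplex or bubble; matching runs
shorter than 2 nt flanked by mismatches are absorbed into the bubble,
because designed "mostly non-complementary" bubbles routinely contain
isolated complementary positions that do not nucleate a duplex. The
minimum-run parameter is exposed.

## Synthetic data: what it emulates, and what it does not

The generator plants known ground truth for every measurement:

* self-avoiding Cα traces (3.8 Å virtual bonds, 2.5 Å clearance) grouped
  into registered domains, moved by exact rigid transforms (rotation about
  the domain centroid plus translation) with optional isotropic Gaussian
  coordinate noise — σ = 0.3 Å in the standard noisy fixture, a simple
  stand-in for coordinate uncertainty in 3–4 Å cryo-EM models;
* ideal cylindrical-fiber B-DNA (rise 3.4 Å, twist 36°/bp; C1′ at 5.8 Å
  radius with ±90° offsets so base-pair midpoints sit exactly on the
  axis; P at 8.91 Å with ±72° offsets giving a 5.79 Å short-diagonal
  minor-groove baseline), with planted kinks (axis break between two
  registers) and per-register groove widenings solved exactly by moving
  each template-strand phosphate away from its cross-strand partners;
* arginine-like probe atoms placed at chosen registers, 3.0 Å from a
  phosphate oxygen, with a ~60/40 template/non-template split;
* random scaffold sequences honoring a requested
  upstream/bubble/downstream/hybrid architecture, rejection-sampled until
  the sequence-level analysis recovers the spec exactly;
* a seven-state "loading plus cycle" ensemble: two states with large
  (tens of degrees, tens of Å) domain displacements and five states along
  a small-rotation chain, reproducing the two-band distance structure and
  a unique minimal-cumulative-RMSD order.

The standard batch (`make_fixture_suite`) contains 20 fixtures covering
rotations of 16–148° (including the 16° step with a 3.5 Å axial COM shift
— the geometry of a one-base-pair translocation), an opening series
peaking at 17.3°, a 31° whole-body wobble, kinks of 7–20°, groove
widenings of 2–3 Å, footprint walks of +9 and −3 registers, and two
scaffold architectures. Everything is byte-deterministic per seed.

What passing these tests does *not* show: the generator has no side
chains, no base atoms beyond C1′, no sequence-dependent helical
variation, no correlated (domain-level) coordinate error, no partial
occupancy or missing density, and its noise is isotropic. Recovery under
these conditions validates the measurement machinery, not the
interpretability of any particular experimental ensemble.

### Recovery tolerances

Noiseless fixtures must recover exactly up to numerics (≤ 10⁻⁴ ° / Å;
observed ≲ 10⁻¹³). Under σ = 0.3 Å noise, angle recovery is required
within 0.5°. The noisy axial COM shift is required within 0.25 Å: the
projection of a COM difference of two 150-residue domains carries
~√(2/N)·σ ≈ 0.035 Å of direct noise plus anchor-fit leverage of similar
size, ~0.06 Å standard error in total, and the band is set at ~4σ of that
propagated error. Kink register must localize within ±1; groove widenings
within 0.1 Å; footprint shifts and scaffold counts exactly.

## Numerical and degenerate-input choices

* Rotation angle clamped into arccos's domain before evaluation; the
  identity rotation reports a conventional axis (x̂).
* Near-180° axes via the symmetrized eigenproblem with a deterministic
  sign choice.
* Screw point computed in the plane perpendicular to the axis
  (minimum-norm least squares), pinning the free axial component to zero.
* Enumeration ties broken lexicographically; anchor ties raised as errors.
* SASA convergence: 96 → 960 → 9600 points agree within 2%; 960 is the
  default as the standard accuracy/cost point.
* Empty contact footprints are valid results; empty selections are errors
  naming the selection.

## Problem sizes

The shipped analyses run on fixtures of 80–150 residues per domain,
24–44 bp duplexes, and a seven-state ensemble (720 enumerated orders);
the full test suite and the acceptance script each complete in seconds on
one CPU. These sizes were chosen as the smallest at which every planted
effect is comfortably above numerical noise; all operations scale to
deposited-model sizes (tens of thousands of atoms), where the pairwise
matrix and SASA stages dominate at a few seconds per state pair.

## Known limitations

* Residue correspondence is by identity of author numbering only; no
  sequence alignment, so cross-species or engineered-construct
  comparisons need a pre-computed mapping.
* No automatic domain segmentation (DynDom-style); domains come from the
  registry.
* No helicoidal base-pair parameter set (roll/twist/slide); bend/kink/
  groove metrics only.
* Interface areas approximate published server values only to ~15%.
* The exact enumeration path orderer refuses n > 12; no heuristic TSP
  fallback is provided, by design.
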