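# Methods

This note records the model behind `fixbox`, the choices that were
genuinely open when it was built, and what the synthetic test systems
do and do not demonstrate.

## Geometry and conventions

The reference box is always treated as triclinic: the five space-filling
box shapes used in simulation are all re-expressible on a triclinic
lattice, so a single representation covers them (conversion to and from
rhombic-dodecahedral or truncated-octahedral layouts is left to the
simulation package's own tools and is out of scope here).  The box
matrix **B** holds the primitive vectors as columns; |det **B**| is the
box volume, and a determinant magnitude below 10⁻⁹ nm³ is rejected as
singular.  Left-handed primitive-vector sets are accepted with a logged
warning — same-handedness with the Cartesian frame is a convenience,
not a requirement.  Any invertible **B** is accepted, although gro
input always yields lower-triangular boxes.

Two conventions exist for the geometric center **g** of the box:
(**b**₁+**b**₂+**b**₃)/2 and the origin.  The default is the half-sum,
which matches the corner-at-origin layout of gro files; `origin` is
selectable everywhere the box is built.

Nearest-integer rounding is ⌈a⌋ = ⌊a + ½⌋ exactly as written: exact
halves round toward +∞ (0.5 → 1, −0.5 → 0).  This is deliberately not
banker's rounding; the half-open wrapped interval [−½, ½) depends on
it.  Scaled-space wrapping, minimum-image vectors, assembly
displacements and molecule wrapping all reduce to this one function, so
its convention is load-bearing.

The minimum-image formula **B**(s − ⌈s⌋) is guaranteed shortest only
for rectangular boxes or when its result is shorter than half the
shortest primitive vector.  Inside this package it is used exclusively
to *rank* candidate nearest pairs, for which occasional overestimation
of a long distance is immaterial; the value is returned even when the
guarantee fails, and callers decide.  Empirically the guarantee as
stated holds on the simulation-legal box family (lower-triangular,
off-diagonal components at most half the diagonals) but can fail for
arbitrarily skewed matrices, so the oracle tests draw their skewed
boxes from the simulation-legal family.

## Proximity

Molecular centers are weighted atom averages with weights summing to 1,
so centers commute with the affine box mapping.  The default weights
are geometric (uniform): the input format carries no masses.  A mass
scheme that guesses the element from the first letter of the atom name
is available but off by default — name-based element guessing is
heuristic and the choice of center barely matters for ranking nearest
molecules.

The default intermolecular measure is the minimum-image-nearest atom
pair, found by an exhaustive |M|·|N| scan.  The center-based measure is
available (`--measure centers`) as the cheap alternative but misranks
elongated molecules whose bulk sits away from the contact interface.
Neither measure is a metric (the triangle inequality can fail); nothing
here relies on metric properties.  No spatial-grid prefilter is
implemented: at the system sizes this package targets (10³–10⁴ atoms,
hundreds of molecules) the exhaustive scan is far from the bottleneck,
and a prefilter would have to be contractually identical to it anyway.
Ties between equal-norm pairs are broken by lowest atom-index pair, and
in the assembly loop by lowest (child id, parent id), purely for
reproducibility.

## Assembly

Displacements follow **K**_child = **K**_parent + ⌈**S**⌋ with **S**
the scaled proximity vector from child to parent measured on the
original coordinates; because integers pass through the rounding, this
is identical to rounding the vector measured against the parent's
*displaced* coordinates, and the equivalence is asserted in tests.
Requiring minimum-image adjacency for *all* pairs simultaneously is
impossible (rounding is not additive — three collinear molecules at
−0.3, 0, +0.3 already fail), which is exactly why the output is a tree.

The seed is the lowest molecule id of the first stage unless a caller
overrides it.  Seed choice shifts the assembled complex by one global
lattice vector, which centering removes; the fixed output is therefore
seed-independent, and this is verified per fixture kind.  The guarantee
assumes distinct pair distances (a unique minimum spanning structure);
exactly degenerate geometries — a perfectly regular lipid lattice — can
make the tree, though not usually the output, depend on tie order.  The
synthetic fixtures jitter their lattices to stay generic.

Later stages attach to the union of *all* previously assembled
molecules, not only the preceding stage, following the reading that new
molecules assemble "on top of the already assembled set".

## Centering and flags

The bounding box is computed per axis from that axis' centering set
only, but the translation is applied to every atom of the system: the
point of the step is to place the whole system consistently, not to
deform it.  Extent checks use strict `> 1` with no tolerance — a set
exactly as wide as the box passes silently.  Flags are `E` (abort the
snapshot), `W` (log and continue), and `I` (silent); `I` and the
default-to-`W` behavior when a `C` line carries no flags are
conveniences for batch pipelines.  Flags are evaluated once, in this
step; they are not re-checked after wrapping.  The rejected alternative
of centering the molecular *center* rather than the bounding box is not
implemented: it mis-centers asymmetric complexes.

## Wrapping

Wrapping is always by molecular center and always per axis.  Putting
the built-in `System` group in all three wrap sets recovers
unconditional wrapping; leaving an axis as `None` preserves structure
that legitimately protrudes (undulation crests).  A molecule whose
center cannot be brought strictly inside stays partially outside with
the smallest achievable protrusion, since the center rule is exactly
the integer translation minimizing the center's distance from the box
center along each wrapped axis.

Re-running the whole pipeline on its own output reproduces it to
floating-point noise.  Note that for complexes with intrinsically
periodic parts (bilayers, the periodic chain) the second run's assembly
step re-unwraps those parts across the boundary and the wrapping step
re-wraps them — the integer shifts cancel exactly per molecule, and
coordinates are unchanged; literal all-zero displacements on re-run
occur only when the assembled complex fits the box without step-4
wrapping (the dimer and micelle kinds).

## The definitions dialect

One global molecule table backs all groups; an atom may belong to at
most one molecule (centers are only well defined over a partition).  A
range or residue run identical to an existing molecule re-uses it;
partial overlap is an error, as is redefining a group name.  `a` lines
carry one range (`first last` or `first-last`).  `n` lines split into
molecules by maximal runs of consecutive atoms sharing residue number
*and* name, so residue numbering that wraps modulo 100000 in large
systems still splits correctly.  `#` comments and blank lines are
ignored; `None` is reserved; `System` (every molecule in the table) is
built in unless the file defines its own.

## gro handling

Reading and writing are self-contained: the pipeline needs
multi-snapshot concatenated streams, per-snapshot boxes
(constant-pressure trajectories breathe), byte-stable
write∘read∘write output, and parse errors that name the offending
line.  Coordinates are nm with three decimals on disk and double
precision in memory, rounded only on write; velocities, when present,
pass through untouched (translations do not change them).  Serial
fields wrap modulo 100000.  Output box vectors always equal input box
vectors — the algorithm never alters the box.

## Synthetic fixtures

Each of the five kinds builds its ground truth analytically: the
complex is laid out whole with generic (jittered) spacings, translated
so the per-axis bounding-box midpoints of the centering sets are
exactly at the box center, and wrap-set molecules are brought in by
their centers.  The broken twin applies per-molecule random lattice
shifts plus one global drift and re-wraps molecule-by-molecule — the
compact whole-molecule output a simulation package would emit.  Ground
truth is thus a fixed point of the algorithm by construction, and
recovery is checked as coordinate equality, not merely equivalence.

Geometry highlights: the membrane kinds choose intra-leaflet spacing
(≈1.0 nm) below the leaflet separation (≈1.6 nm) so assembly walks each
leaflet — the documented spreading behavior — while the box height
keeps the through-boundary leaflet distance (≥2.7 nm) safely larger, so
leaflets attach on the correct side.  The bridged-cluster kind places a
chain of lipids 0.5–0.9 nm apart running from beside one protein
through the box boundary to beside another protein's image, with
protein–protein gaps ≈1.5 nm: merged single-stage assembly provably
follows the chain and displaces that protein by one box, while staged
assembly keeps the cluster whole.  The periodic chain closes on itself
through the boundary with distinct inter-unit gaps, so its spanning
structure is unique and the cut bond is deterministic.

Fixture scale is a few hundred atoms per system (≤ 5000 by
construction) so that exhaustive quadratic oracles remain instant; the
acceptance sweep (5 kinds × 20 seeds, full pipeline plus oracle
comparisons) completes in a few seconds.  What passing these tests
shows: exact recovery of molecule-wise lattice breakage, staging
semantics, flag semantics, and format stability.  What they do not
show: behavior on systems violating the whole-molecule input
assumption, multiple separate aggregates (known to be handled
sub-optimally — each aggregate would need its own run or staging),
steric plausibility, or performance at millions of atoms.

## Numerical notes

Everything is double precision; the only intentional quantization is
the 0.001 nm gro write precision.  Recovery tolerances in tests are
10⁻⁹ nm in memory and 10⁻³ nm through files.  Degenerate inputs are
handled as follows: empty stages warn and are skipped; empty centering
sets are errors (no bounding box exists); an empty wrap set is simply
inert; a singular box or an atom outside the serial range is an error
at parse time.
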