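# fixbox

Make a broken molecular complex whole again in a periodic simulation box.

Molecular-dynamics simulations use periodic boundary conditions (PBC):
the triclinic reference box is surrounded by identical replicas, and any
atom leaving through one face re-enters through the opposite one.  As a
heterogeneous system drifts, the complex of interest — a multi-subunit
protein, a peptide on a bilayer, a micelle — ends up "broken" across
the box faces: its parts sit in different periodic images even though,
minimum-image-wise, nothing dissociated.  Analyses and visualizations
that need the complex as one object in one box then fail, and fitting
to a reference structure is unreliable whenever parts move relative to
each other.

`fixbox` fixes such configurations from a minimal declarative
description of the system — which atoms form which molecules, in what
order the parts should be reassembled, which parts define the centering
per axis, and which molecules may be wrapped along which axes.  No
force-field topology is required.  It is aimed at people
post-processing trajectories before analysis, and at automated
pipelines (e.g. periodic Poisson–Boltzmann runs) where per-frame manual
fixing is not an option.

## The algorithm

All periodic bookkeeping happens in *scaled coordinates*.  With the
primitive vectors **b**₁, **b**₂, **b**₃ as columns of the box matrix
**B** and **g** the box center,

    s = B⁻¹ (r − g),

which maps the triclinic box to a unit cube centered at the origin.
With the nearest-integer function ⌈a⌋ = ⌊a + ½⌋, wrapping is
s° = s − ⌈s⌋ (components in [−½, ½)) and the minimum-image vector for a
scaled separation s is **B**(s − ⌈s⌋).  Four steps follow:

1. **Proximity.** The distance between molecules M and N is measured
   either between weighted molecular centers or — the default — by the
   minimum-image-nearest atom pair over all pairs (k ∈ M, l ∈ N), which
   matches the intuitive notion of contact even for elongated molecules.
2. **Assembly.** Starting from a seed molecule with **K** = 0, the
   closest (unassembled, assembled) pair is linked greedily and the
   newcomer inherits the integer lattice displacement
   **K**_M = **K**_N + ⌈**S**_MN⌋ from its parent; every atom of M moves
   by **B K**_M, so intramolecular geometry is untouched.  The links
   form a tree whose relative arrangement does not depend on the seed.
   Assembly may run in stages (e.g. protein subunits first, lipids on
   top of them) to stop chains of mutually close small molecules from
   dragging subunits into different images.
3. **Centering.** Per axis, the bounding box of a chosen molecule set
   is computed in scaled space, and one rigid translation moves its
   midpoint to the origin — affine maps keep it centered in physical
   space too.  A set wider than the box along an axis triggers a
   per-axis error/warn/ignore flag.
4. **Wrapping.** Molecules of per-axis wrap sets whose *center* lies
   outside the box are translated in by an integer number of boxes
   along that axis only — never per atom, and e.g. never vertically for
   an undulating bilayer if the vertical set is left empty.

## Worked example

The package ships a generator of synthetic broken systems with known
ground truth.  Writing one broken peptide-on-bilayer snapshot and its
definitions file, then fixing it:

```python
from fixbox import FixtureSpec, generate, write_file
broken, truth, defs = generate(FixtureSpec("membrane_peptide", seed=1))
write_file("broken.gro", [broken])
open("defs.txt", "w").write(defs)
```

The definitions file declares the groups, the two assembly stages, the
per-axis centering sets with flags, and the per-axis wrap sets (`None`
means "wrap nothing along z", preserving bilayer undulations):

```
G Peptide
a 1 24
G Bilayer
n LIP
G Complex
g Peptide
g Bilayer
G Water
n SOL
A Peptide
A Bilayer
C Peptide Peptide Complex E E W
P System System Water
```

```sh
$ fixbox -f broken.gro -d defs.txt -o fixed.gro -v
INFO fixbox.assembly: assembled stage 1 (Peptide): 1 molecules
INFO fixbox.assembly: assembled stage 2 (Bilayer): 72 molecules
INFO fixbox: snapshot 1: 72 assembly edges, scaled extent (0.156, 0.157, 0.661)
```

The 72 assembly edges are the nearest-neighbor tree over peptide and
lipids; the scaled extents are the per-axis bounding-box widths of the
centering sets (all below 1, so the complex fits the box and the
`E E W` flags stay quiet).  `fixed.gro` holds the same atoms and box
with the peptide centered on the membrane plane, the bilayer whole
beneath it, and every water molecule wrapped back inside — it matches
the generator's ground-truth coordinates to the 0.001 nm precision of
the format.  Multi-snapshot files are processed frame by frame, each
with its own box.

Exit codes: 0 success, 1 structure parse error, 2 definitions error,
3 a centering set flagged `E` overflowed the box, 4 anything else.

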