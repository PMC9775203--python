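"""Synthetic periodic systems with known fixed ground truth.

Each fixture kind emulates a class of simulated system whose complex of
interest tends to break across periodic boundaries:

``dimer``
    a two-monomer protein complex in water, in a skewed triclinic box;
``membrane_peptide``
    a peptide adsorbed on a two-leaflet lipid bilayer, with intra-leaflet
    lipid spacing smaller than the leaflet separation, so nearest-neighbor
    assembly walks each leaflet separately;
``multi_protein_bilayer``
    several proteins on a lipid layer engineered so that a chain of
    mutually close lipids connects one protein to the periodic image of
    another — the scenario where single-stage assembly tears the protein
    cluster apart and staging is required;
``micelle``
    a radial aggregate of amphiphiles in water;
``infinite_polymer``
    a strictly periodic chain spanning the box, treated as per-unit
    "molecules" so the assembly machinery can rebuild it without any
    notion of bonds.

The generator builds the *ground truth* analytically: the complex is
laid out whole, translated so the per-axis bounding boxes of the
centering sets sit exactly at the box center, and molecules of the
wrapping sets are brought in by their centers.  The *broken* twin then
differs from the truth only by per-molecule integer lattice shifts plus
one global drift, re-wrapped molecule-by-molecule into the box the way
simulation software emits configurations (molecules stay whole
throughout).  Fixing the broken twin must therefore reproduce the truth
coordinates exactly, which end-to-end tests assert to output precision.

No physical realism is attempted beyond spacings: there are no force
fields and no sterics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .defsfile import FixPlan, Group, Topology
from .errors import TopologyError
from .groio import AtomRecord, Configuration
from .triclinic import TriclinicBox, make_box, to_physical, to_scaled

KINDS = ("dimer", "membrane_peptide", "multi_protein_bilayer",
         "micelle", "infinite_polymer")


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: a system kind and the seed that fixes everything."""

    kind: str
    seed: int
    n_waters: int | None = None   # per-kind default when None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


class _Molecule:
    """Generator-internal molecule: residue name, atom names, scaled coords."""

    def __init__(self, resname: str, s: np.ndarray, names=None):
        self.resname = resname
        self.s = np.asarray(s, dtype=float)
        n = len(self.s)
        self.names = list(names) if names else [f"C{i+1}" for i in range(n)]


def _blob(rng: np.random.Generator, center, radii, n: int) -> np.ndarray:
    """n points uniform in an axis-aligned ellipsoid-ish cube (scaled)."""
    return np.asarray(center) + rng.uniform(-1.0, 1.0, (n, 3)) * np.asarray(radii)


def _water(rng: np.random.Generator) -> _Molecule:
    center = rng.uniform(-0.44, 0.44, 3)
    offsets = np.array([[0.0, 0.0, 0.0],
                        [0.016, 0.01, 0.0],
                        [-0.012, 0.012, 0.008]])
    return _Molecule("SOL", center + offsets, ["OW", "HW1", "HW2"])


# ---------------------------------------------------------------------------
# kind builders: return (box, complex molecules, per-axis centering molecule
# indices, per-molecule wrap axes, defs text, default water count)

def _build_dimer(rng):
    box = make_box((5.0, 0, 0), (1.0, 5.0, 0), (0, 0, 5.0))
    a = _Molecule("PRA", _blob(rng, (-0.11, 0.0, 0.0), (0.09, 0.06, 0.06), 30))
    b = _Molecule("PRB", _blob(rng, (0.11, 0.0, 0.0), (0.09, 0.06, 0.06), 30))
    mols = [a, b]
    c_sets = ([0, 1], [0, 1], [0, 1])
    wrap_axes = {0: (0, 1, 2), 1: (0, 1, 2)}
    defs = (
        "# synthetic two-monomer complex in water\n"
        "G Dimer\na 1 30\na 31 60\n"
        "G Water\nn SOL\n"
        "A Dimer\n"
        "C Dimer Dimer Dimer W W W\n"
        "P System System System\n"
    )
    return box, mols, c_sets, wrap_axes, defs, 60


def _build_membrane_peptide(rng):
    box = make_box((6.0, 0, 0), (0, 6.0, 0), (0, 0, 8.0))
    peptide = _Molecule(
        "PEP",
        to_scaled(_blob(rng, (4.2, 3.0, 6.9), (0.5, 0.5, 0.4), 24), box),
    )
    mols = [peptide]
    # two leaflets of a 6x6 lipid grid; heads out, tails facing each other
    for leaflet, z_levels in (("upper", (6.0, 5.4, 4.8)),
                              ("lower", (2.0, 2.6, 3.2))):
        for i in range(6):
            for j in range(6):
                x = 0.5 + i + rng.uniform(-0.12, 0.12)
                y = 0.5 + j + rng.uniform(-0.12, 0.12)
                pos = np.array([[x, y, z] for z in z_levels])
                mols.append(_Molecule("LIP", to_scaled(pos, box),
                                      ["LH", "LM", "LT"]))
    lipid_ids = list(range(1, len(mols)))
    c_sets = ([0], [0], [0] + lipid_ids)
    wrap_axes = {0: (0, 1)}
    wrap_axes.update({i: (0, 1) for i in lipid_ids})
    defs = (
        "# synthetic peptide on a lipid bilayer\n"
        "G Peptide\na 1 24\n"
        "G Bilayer\nn LIP\n"
        "G Complex\ng Peptide\ng Bilayer\n"
        "G Water\nn SOL\n"
        "A Peptide\nA Bilayer\n"
        "C Peptide Peptide Complex E E W\n"
        "P System System Water\n"
    )
    return box, mols, c_sets, wrap_axes, defs, 80


def _build_multi_protein_bilayer(rng):
    box = make_box((12.0, 0, 0), (0, 5.0, 0), (0, 0, 5.0))
    proteins = [
        _Molecule("PRO", to_scaled(_blob(rng, c, (0.25, 0.25, 0.25), 8), box))
        for c in ((5.5, 2.5, 3.6), (7.5, 2.5, 3.6), (5.5, 3.8, 3.6))
    ]
    # a chain of mutually close lipids running from beside protein 1,
    # through the -x boundary, to beside the periodic image of protein 2
    chain_x = [5.4, 4.7, 4.0, 3.3, 2.6, 1.9, 1.2, 0.3,
               11.8, 11.1, 10.4, 9.7, 9.0, 8.3, 7.6]
    lipids = []
    for x in chain_x:
        x = x + rng.uniform(-0.02, 0.02)
        y = 2.5 + rng.uniform(-0.02, 0.02)
        pos = np.array([[x, y, 2.0], [x, y, 2.4]])
        lipids.append(_Molecule("LIP", to_scaled(pos, box), ["LH", "LT"]))
    mols = proteins + lipids
    lipid_ids = list(range(3, len(mols)))
    c_sets = ([0, 1, 2], [0, 1, 2], [0, 1, 2] + lipid_ids)
    wrap_axes = {i: (0, 1) for i in range(len(mols))}
    defs = (
        "# synthetic protein cluster bridged by a lipid chain\n"
        "G Proteins\na 1 8\na 9 16\na 17 24\n"
        "G Bilayer\nn LIP\n"
        "G Complex\ng Proteins\ng Bilayer\n"
        "G Water\nn SOL\n"
        "A Proteins\nA Bilayer\n"
        "C Proteins Proteins Complex W W W\n"
        "P System System Water\n"
    )
    return box, mols, c_sets, wrap_axes, defs, 50


def _build_micelle(rng):
    box = make_box((6.0, 0, 0), (0, 6.0, 0), (0, 0, 6.0))
    center = np.array([3.4, 2.7, 3.2])
    n_amphiphiles = 10
    mols = []
    # quasi-uniform directions from a golden spiral; heads point outward
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n_amphiphiles):
        cos_t = 1.0 - 2.0 * (i + 0.5) / n_amphiphiles
        sin_t = np.sqrt(1.0 - cos_t ** 2)
        phi = golden * i
        u = np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
        radii = np.array([0.45, 0.75, 1.05, 1.35])
        pos = center + radii[:, None] * u + rng.uniform(-0.03, 0.03, (4, 3))
        mols.append(_Molecule("AMP", to_scaled(pos, box),
                              ["T1", "T2", "M1", "H1"]))
    ids = list(range(len(mols)))
    c_sets = (ids, ids, ids)
    wrap_axes = {i: (0, 1, 2) for i in ids}
    defs = (
        "# synthetic amphiphile micelle in water\n"
        "G Micelle\nn AMP\n"
        "G Water\nn SOL\n"
        "A Micelle\n"
        "C Micelle Micelle Micelle W W W\n"
        "P System System System\n"
    )
    return box, mols, c_sets, wrap_axes, defs, 60


def _build_infinite_polymer(rng):
    box = make_box((8.0, 0, 0), (0, 5.0, 0), (0, 0, 5.0))
    solute = _Molecule(
        "SLT", to_scaled(_blob(rng, (4.0, 3.7, 2.5), (0.25, 0.25, 0.25), 8), box)
    )
    mols = [solute]
    n_units = 10
    for j in range(n_units):
        base = 0.1 + 0.8 * j
        xs = base + np.array([0.0, 0.27, 0.54]) + rng.uniform(-0.03, 0.03, 3)
        pos = np.column_stack([
            xs,
            2.5 + rng.uniform(-0.02, 0.02, 3),
            2.5 + rng.uniform(-0.02, 0.02, 3),
        ])
        mols.append(_Molecule("UNT", to_scaled(pos, box)))
    unit_ids = list(range(1, len(mols)))
    c_sets = ([0], [0], [0])
    wrap_axes = {i: (0, 1, 2) for i in range(len(mols))}
    defs = (
        "# synthetic periodic chain, one molecule per structural unit\n"
        "G Solute\na 1 8\n"
        "G Chain\nn UNT\n"
        "G Water\nn SOL\n"
        "A Solute\nA Chain\n"
        "C Solute Solute Solute W W W\n"
        "P System System System\n"
    )
    return box, mols, c_sets, wrap_axes, defs, 40


_BUILDERS = {
    "dimer": _build_dimer,
    "membrane_peptide": _build_membrane_peptide,
    "multi_protein_bilayer": _build_multi_protein_bilayer,
    "micelle": _build_micelle,
    "infinite_polymer": _build_infinite_polymer,
}


def _round_half_up(a: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(a, dtype=float) + 0.5)


def _as_configuration(title: str, mols: list[_Molecule],
                      box: TriclinicBox) -> Configuration:
    atoms = []
    serial = 0
    for residue_number, mol in enumerate(mols, start=1):
        positions = to_physical(mol.s, box)
        for name, position in zip(mol.names, positions):
            serial += 1
            atoms.append(AtomRecord(
                residue_number=residue_number,
                residue_name=mol.resname,
                atom_name=name,
                atom_number=serial,
                position=tuple(float(x) for x in position),
            ))
    return Configuration(title=title, atoms=atoms, box=box)


def generate(spec: FixtureSpec) -> tuple[Configuration, Configuration, str]:
    """Build one fixture: ``(broken, ground_truth, definitions_text)``.

    The same spec (kind and seed) always yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    box, mols, c_sets, wrap_axes, defs, default_waters = \
        _BUILDERS[spec.kind](rng)

    # translate so the per-axis bounding boxes of the centering sets sit
    # exactly at the box center (the origin of scaled space)
    translation = np.zeros(3)
    for axis in range(3):
        component = np.concatenate([mols[i].s[:, axis] for i in c_sets[axis]])
        translation[axis] = (component.min() + component.max()) / 2.0
    for mol in mols:
        mol.s = mol.s - translation

    # bring wrap-set molecules in by their (geometric) centers, exactly
    # as step 4 of the pipeline will
    for index, axes in wrap_axes.items():
        center = mols[index].s.mean(axis=0)
        shift = np.zeros(3)
        axes = list(axes)
        shift[axes] = _round_half_up(center)[axes]
        mols[index].s = mols[index].s - shift

    n_waters = spec.n_waters if spec.n_waters is not None else default_waters
    mols.extend(_water(rng) for _ in range(n_waters))

    truth = _as_configuration(
        f"synthetic {spec.kind} fixture seed={spec.seed} (ground truth)",
        mols, box,
    )

    # breakage: per-molecule lattice shifts plus one global drift, then
    # molecule-center re-wrapping into the box (what simulation software
    # emits); molecules stay whole throughout
    drift = rng.uniform(-0.75, 0.75, 3)
    broken_mols = []
    for mol in mols:
        shift = rng.integers(-2, 3, 3).astype(float)
        s = mol.s + drift + shift
        s = s - _round_half_up(s.mean(axis=0))
        broken_mols.append(_Molecule(mol.resname, s, mol.names))
    broken = _as_configuration(
        f"synthetic {spec.kind} fixture seed={spec.seed} (broken)",
        broken_mols, box,
    )
    return broken, truth, defs


def equivalent_up_to_lattice(cfg_a: Configuration, cfg_b: Configuration,
                             topology: Topology, tolerance: float = 1e-6,
                             ) -> tuple[bool, dict[int, np.ndarray]]:
    """Do two snapshots differ only by molecule-wise lattice translations?

    Returns ``(flag, shifts)``: ``flag`` is true when ``cfg_a`` equals
    ``cfg_b`` up to one global translation plus an integer lattice shift
    per molecule; ``shifts`` then maps molecule id to that integer shift,
    measured relative to the first molecule (whose shift is zero by
    convention).
    """
    if cfg_a.n_atoms != cfg_b.n_atoms:
        raise TopologyError(
            f"atom counts differ: {cfg_a.n_atoms} vs {cfg_b.n_atoms}"
        )
    diff = (to_scaled(cfg_a.positions, cfg_a.box)
            - to_scaled(cfg_b.positions, cfg_b.box))
    reference: np.ndarray | None = None
    shifts: dict[int, np.ndarray] = {}
    for molecule in topology.molecules:
        d = diff[molecule.indices]
        mean = d.mean(axis=0)
        if np.abs(d - mean).max() > tolerance:
            return False, {}
        if reference is None:
            reference = mean
        relative = mean - reference
        rounded = np.round(relative)
        if np.abs(relative - rounded).max() > tolerance:
            return False, {}
        shifts[molecule.molecule_id] = rounded.astype(np.int64)
    return True, shifts


def single_stage_plan(plan: FixPlan) -> FixPlan:
    """The same plan with all assembly stages merged into one.

    Used to demonstrate why staging matters: on systems where small
    molecules chain between images of the large ones, the merged variant
    tears the large-molecule cluster apart.
    """
    merged: dict[int, None] = {}
    for stage in plan.assembly_stages:
        merged.update(dict.fromkeys(stage.molecule_ids))
    return FixPlan(
        topology=plan.topology,
        groups=plan.groups,
        assembly_stages=[Group("merged", tuple(merged))],
        centering_sets=plan.centering_sets,
        centering_flags=plan.centering_flags,
        wrapping_sets=plan.wrapping_sets,
    )
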