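"""The definitions file: molecules, groups, stages, centering, wrapping.

The file is parsed line by line; the first whitespace-separated token of
each line is its key:

``G name``
    start a new named group; subsequent ``a``/``n``/``g`` lines add to it
``a first [last]``
    one molecule made of the inclusive atom-serial range ``first..last``
``n resname``
    one molecule per maximal run of consecutive atoms sharing residue
    number and bearing this residue name
``g name``
    merge a previously defined group into the current one
``A name``
    an assembly stage; successive ``A`` lines are stages 1, 2, ...
``C gx gy gz [fx fy fz]``
    the per-axis centering groups and their flags (E = error,
    W = warn, I = ignore; default W)
``P gx gy gz``
    the per-axis wrapping groups

Lines starting with ``#`` and blank lines are skipped.  Two group names
are built in: ``None`` is the empty set, and ``System`` (all molecules
known to the plan) is available wherever a group is referenced unless
the file defines its own ``System``.

Molecules live in one global table: an atom may belong to at most one
molecule, because molecular centers are only well defined over a
partition.  A range or residue run that exactly coincides with an
existing molecule re-uses it; a partial overlap is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DefsError
from .groio import Configuration

logger = logging.getLogger(__name__)

AXES = ("x", "y", "z")


class Flag(Enum):
    """What to do when a centering set is wider than the box along an axis."""

    ERROR = "E"
    WARN = "W"
    IGNORE = "I"


@dataclass(frozen=True)
class MoleculeSpec:
    """One molecule: an id and its ordered set of 1-based atom serials."""

    molecule_id: int
    atom_serials: tuple[int, ...]

    def __post_init__(self):
        if not self.atom_serials:
            raise DefsError(f"molecule {self.molecule_id} has no atoms")

    @property
    def indices(self) -> np.ndarray:
        """0-based atom indices into the configuration arrays."""
        return np.asarray(self.atom_serials, dtype=np.intp) - 1


class Topology:
    """Partition of the atoms into molecules (grown while parsing)."""

    def __init__(self, n_atoms: int):
        self.n_atoms = n_atoms
        self.molecules: list[MoleculeSpec] = []
        self._by_atoms: dict[tuple[int, ...], MoleculeSpec] = {}
        # occupancy: atom serial -> molecule id, for overlap detection
        self._owner: dict[int, int] = {}

    def by_id(self, molecule_id: int) -> MoleculeSpec:
        return self.molecules[molecule_id - 1]

    def add_molecule(self, serials: tuple[int, ...],
                     line_number: int | None = None) -> MoleculeSpec:
        """Register a molecule, re-using an identical existing one."""
        existing = self._by_atoms.get(serials)
        if existing is not None:
            return existing
        for serial in serials:
            if serial < 1 or serial > self.n_atoms:
                raise DefsError(
                    f"atom serial {serial} outside 1..{self.n_atoms}",
                    line_number,
                )
            owner = self._owner.get(serial)
            if owner is not None:
                raise DefsError(
                    f"atom {serial} already belongs to molecule {owner}; "
                    "molecules must be disjoint",
                    line_number,
                )
        molecule = MoleculeSpec(len(self.molecules) + 1, serials)
        self.molecules.append(molecule)
        self._by_atoms[serials] = molecule
        for serial in serials:
            self._owner[serial] = molecule.molecule_id
        return molecule


@dataclass(frozen=True)
class Group:
    """A named, ordered set of molecules."""

    name: str
    molecule_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.molecule_ids)


@dataclass
class FixPlan:
    """Everything the pipeline needs beyond the coordinates themselves."""

    topology: Topology
    groups: dict[str, Group]
    assembly_stages: list[Group]
    centering_sets: tuple[Group, Group, Group]
    centering_flags: tuple[Flag, Flag, Flag]
    wrapping_sets: tuple[Group, Group, Group]


def resolve_residue_molecules(config: Configuration,
                              residue_name: str) -> list[tuple[int, ...]]:
    """Atom-serial runs for every single-residue molecule named ``residue_name``.

    A molecule is a maximal run of consecutive atoms sharing both residue
    number and residue name; grouping by runs rather than by number alone
    keeps molecules intact when residue numbering wraps modulo 100000 in
    very large systems.  Returns one serial tuple per molecule, in file
    order.  An absent residue name yields an empty list and a logged
    warning.
    """
    runs: list[tuple[int, ...]] = []
    current: list[int] = []
    previous_key = None
    for index, atom in enumerate(config.atoms):
        key = (atom.residue_number, atom.residue_name)
        if key != previous_key and current:
            runs.append(tuple(current))
            current = []
        if atom.residue_name == residue_name:
            current.append(index + 1)
        previous_key = key
    if current:
        runs.append(tuple(current))
    if not runs:
        logger.warning(
            "residue name %r matches no atoms; empty contribution",
            residue_name,
        )
    return runs


def _require(condition: bool, message: str, line_number: int) -> None:
    if not condition:
        raise DefsError(message, line_number)


def parse_definitions(text: str, config: Configuration) -> FixPlan:
    """Parse definitions text into a validated :class:`FixPlan`.

    ``config`` supplies the atom table needed to resolve ``n`` lines and
    to bound atom-serial ranges.
    """
    topology = Topology(config.n_atoms)
    groups: dict[str, Group] = {}
    stage_names: list[tuple[str, int]] = []
    centering: tuple[list[str], list[str], int] | None = None  # names, flags, line
    wrapping: tuple[list[str], int] | None = None

    current_name: str | None = None
    current_members: list[int] = []  # molecule ids, insertion-ordered

    def close_group(line_number: int) -> None:
        nonlocal current_name, current_members
        if current_name is None:
            return
        # preserve order, drop duplicates
        seen: dict[int, None] = dict.fromkeys(current_members)
        groups[current_name] = Group(current_name, tuple(seen))
        current_name, current_members = None, []

    def add_members(ids) -> None:
        current_members.extend(ids)

    for line_number, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        key, args = tokens[0], tokens[1:]

        if key == "G":
            close_group(line_number)
            _require(len(args) == 1, "G line takes exactly one group name",
                     line_number)
            name = args[0]
            _require(name != "None", "group name 'None' is reserved",
                     line_number)
            _require(name not in groups,
                     f"group {name!r} defined twice", line_number)
            current_name = name
        elif key == "a":
            _require(current_name is not None,
                     "'a' line outside a group definition", line_number)
            _require(len(args) in (1, 2),
                     "'a' line takes one atom range (first [last] or first-last)",
                     line_number)
            try:
                if len(args) == 1 and "-" in args[0]:
                    lo_text, hi_text = args[0].split("-", 1)
                    lo, hi = int(lo_text), int(hi_text)
                elif len(args) == 1:
                    lo = hi = int(args[0])
                else:
                    lo, hi = int(args[0]), int(args[1])
            except ValueError:
                raise DefsError(f"unparsable atom range: {' '.join(args)!r}",
                                line_number)
            _require(lo <= hi, f"empty atom range {lo}-{hi}", line_number)
            molecule = topology.add_molecule(tuple(range(lo, hi + 1)),
                                             line_number)
            add_members([molecule.molecule_id])
        elif key == "n":
            _require(current_name is not None,
                     "'n' line outside a group definition", line_number)
            _require(len(args) == 1, "'n' line takes one residue name",
                     line_number)
            runs = resolve_residue_molecules(config, args[0])
            add_members(
                topology.add_molecule(run, line_number).molecule_id
                for run in runs
            )
        elif key == "g":
            _require(current_name is not None,
                     "'g' line outside a group definition", line_number)
            _require(len(args) == 1, "'g' line takes one group name",
                     line_number)
            referenced = groups.get(args[0])
            _require(referenced is not None,
                     f"reference to undefined group {args[0]!r}", line_number)
            add_members(referenced.molecule_ids)
        elif key == "A":
            close_group(line_number)
            _require(len(args) == 1, "A line takes exactly one group name",
                     line_number)
            stage_names.append((args[0], line_number))
        elif key == "C":
            close_group(line_number)
            _require(centering is None, "duplicate C line", line_number)
            _require(len(args) in (3, 6),
                     "C line takes three group names and optionally three flags",
                     line_number)
            centering = (args[:3], args[3:6], line_number)
        elif key == "P":
            close_group(line_number)
            _require(wrapping is None, "duplicate P line", line_number)
            _require(len(args) == 3, "P line takes three group names",
                     line_number)
            wrapping = (args[:3], line_number)
        else:
            raise DefsError(f"unknown line key {key!r}", line_number)
    close_group(0)

    # Built-in groups.  A user-defined System shadows the builtin.
    builtins: dict[str, Group] = {"None": Group("None", ())}
    if "System" not in groups:
        builtins["System"] = Group(
            "System",
            tuple(m.molecule_id for m in topology.molecules),
        )
        logger.debug("using built-in group System (%d molecules)",
                     len(builtins["System"]))

    def lookup(name: str, line_number: int) -> Group:
        group = groups.get(name) or builtins.get(name)
        _require(group is not None,
                 f"reference to undefined group {name!r}", line_number)
        return group

    stages = [lookup(name, ln) for name, ln in stage_names]
    claimed: dict[int, str] = {}
    for stage in stages:
        for molecule_id in stage.molecule_ids:
            if molecule_id in claimed:
                raise DefsError(
                    f"assembly stages overlap: molecule {molecule_id} is in "
                    f"both {claimed[molecule_id]!r} and {stage.name!r}"
                )
            claimed[molecule_id] = stage.name

    if centering is None:
        raise DefsError("missing C line (per-axis centering sets)")
    names, flag_tokens, c_line = centering
    centering_sets = tuple(lookup(name, c_line) for name in names)
    if not flag_tokens:
        flags = (Flag.WARN, Flag.WARN, Flag.WARN)
        logger.debug("C line carries no flags; defaulting to W W W")
    else:
        parsed_flags = []
        for token in flag_tokens:
            try:
                parsed_flags.append(Flag(token))
            except ValueError:
                raise DefsError(
                    f"unknown centering flag {token!r} (expected E, W or I)",
                    c_line,
                )
        flags = tuple(parsed_flags)
    for flag in flags:
        if flag is Flag.IGNORE:
            logger.info("centering flag I: extent overflows will be ignored")

    if wrapping is None:
        raise DefsError("missing P line (per-axis wrapping sets)")
    wrap_names, p_line = wrapping
    wrapping_sets = tuple(lookup(name, p_line) for name in wrap_names)

    return FixPlan(
        topology=topology,
        groups={**builtins, **groups},
        assembly_stages=stages,
        centering_sets=centering_sets,
        centering_flags=flags,
        wrapping_sets=wrapping_sets,
    )
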