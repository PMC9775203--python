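"""Molecule-wise wrapping into the reference box.

The last step moves molecules that ended up outside the box (scattered
lipids of a periodic bilayer, solvent displaced by the centering
translation) back inside, one integer box count per axis.  The shift is
computed from the *molecular center*, never per atom — per-atom wrapping
would cut molecules across the box faces.  Wrapping is conditional per
axis: each axis has its own molecule set, so e.g. bilayer lipids can be
wrapped in the membrane plane while leaving the normal direction
untouched to preserve undulation crests.

A molecule whose center cannot be brought strictly inside stays
partially outside, but with the smallest protruding portion any integer
translation can achieve.
"""

from __future__ import annotations

import numpy as np

from .defsfile import Group, Topology
from .proximity import CenterWeights, molecular_center
from .triclinic import TriclinicBox, nearest_int, to_physical


def wrap_molecules(wrap_sets: tuple[Group, Group, Group],
                   topology: Topology,
                   scaled_positions: np.ndarray,
                   weights: CenterWeights,
                   ) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Wrap each set's molecules along its axis by the center rule.

    For molecule M in the axis-α set, every atom of M gets
    ``s''' = s'' - round(center_α(M))`` in that component; other
    components and other molecules are untouched.  Afterwards each
    wrapped molecule's center α-component lies in [-1/2, 1/2).

    Returns the new scaled positions and the per-molecule integer shift
    actually applied (only molecules in at least one set appear).
    """
    s_new = np.array(scaled_positions, dtype=float, copy=True)
    members: dict[int, list[int]] = {}
    for axis, group in enumerate(wrap_sets):
        for molecule_id in group.molecule_ids:
            members.setdefault(molecule_id, []).append(axis)
    shifts: dict[int, np.ndarray] = {}
    for molecule_id, axes in members.items():
        molecule = topology.by_id(molecule_id)
        center = molecular_center(molecule, scaled_positions, weights)
        shift = np.zeros(3, dtype=np.int64)
        shift[axes] = nearest_int(center)[axes]
        shifts[molecule_id] = shift
        if shift.any():
            s_new[molecule.indices] -= shift
    return s_new, shifts


def finalize(scaled_positions: np.ndarray, box: TriclinicBox) -> np.ndarray:
    """Map final scaled coordinates back to physical positions (nm)."""
    return to_physical(scaled_positions, box)
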