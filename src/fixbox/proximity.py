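"""Intermolecular proximity under periodic boundary conditions.

Two measures of the distance between molecules M and N are supported,
both expressed in scaled coordinates so that physical and scaled
versions map onto each other through the box matrix:

* the vector between the two molecular *centers* (weighted atom
  averages), cheap but misleading for elongated molecules whose bulk
  sits away from their contact interface;
* the interatomic vector of the *minimum-image nearest atom pair*,
  quadratic in the atom counts but matching the intuitive notion of
  which molecules touch.  This is the default everywhere in the
  package.

The norm of either measure is a proximity score, not a metric: the
triangle inequality can fail, which is harmless because the assembly
step only ever ranks candidate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .defsfile import MoleculeSpec, Topology
from .triclinic import TriclinicBox, wrap_scaled

# rough atomic masses for the optional mass-weighting scheme, keyed on
# the first alphabetic character of the atom name (gro carries no masses)
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "F": 18.998, "K": 39.098,
}
_DEFAULT_MASS = 12.011


class WeightScheme(Enum):
    GEOMETRIC = "geometric"
    MASS = "mass"


class CenterWeights:
    """Per-molecule normalized atom weights defining molecular centers.

    ``geometric`` gives every atom of a molecule the same weight (the
    default: the input format carries no masses).  ``mass`` guesses an
    element from the leading letter of each atom name and weights by
    atomic mass.
    """

    def __init__(self, topology: Topology, atoms=None,
                 scheme: WeightScheme = WeightScheme.GEOMETRIC):
        self.scheme = scheme
        self._weights: dict[int, np.ndarray] = {}
        for molecule in topology.molecules:
            n = len(molecule.atom_serials)
            if scheme is WeightScheme.GEOMETRIC:
                w = np.full(n, 1.0 / n)
            else:
                if atoms is None:
                    raise ValueError(
                        "mass weighting needs the atom records to guess elements"
                    )
                masses = np.array([
                    _guess_mass(atoms[i].atom_name)
                    for i in molecule.indices
                ])
                w = masses / masses.sum()
            self._weights[molecule.molecule_id] = w

    def for_molecule(self, molecule: MoleculeSpec) -> np.ndarray:
        return self._weights[molecule.molecule_id]


def _guess_mass(atom_name: str) -> float:
    for char in atom_name:
        if char.isalpha():
            return _ELEMENT_MASSES.get(char.upper(), _DEFAULT_MASS)
    return _DEFAULT_MASS


def molecular_center(molecule: MoleculeSpec, scaled_positions: np.ndarray,
                     weights: CenterWeights) -> np.ndarray:
    """Weighted center of a molecule in scaled coordinates.

    Because the weights sum to one, mapping this center to physical
    space gives exactly the weighted center of the physical positions
    (centers commute with the affine box mapping).
    """
    w = weights.for_molecule(molecule)
    return w @ scaled_positions[molecule.indices]


def center_distance(M: MoleculeSpec, N: MoleculeSpec,
                    scaled_positions: np.ndarray,
                    weights: CenterWeights) -> np.ndarray:
    """Scaled vector from the center of M to the center of N."""
    return (molecular_center(N, scaled_positions, weights)
            - molecular_center(M, scaled_positions, weights))


@dataclass(frozen=True)
class ProximityResult:
    """Nearest minimum-image atom pair between two molecules.

    ``k``/``l`` are 0-based atom indices (``k`` in M, ``l`` in N),
    ``scaled_vector`` is the raw (unwrapped) scaled vector from atom k to
    atom l, ``vector`` the physical minimum-image vector and ``norm`` its
    length in nm.  Note that the scaled vector is generally *not* the
    shortest pair vector in scaled space: affine maps preserve length
    ratios only along parallel directions.
    """

    k: int
    l: int
    vector: np.ndarray
    norm: float
    scaled_vector: np.ndarray


def min_pair_distance(M: MoleculeSpec, N: MoleculeSpec,
                      scaled_positions: np.ndarray,
                      box: TriclinicBox) -> ProximityResult:
    """The atom pair of (M, N) with the shortest minimum-image distance.

    Exhaustive over all ``|M| x |N|`` pairs; ties are broken by the
    lexicographically lowest ``(k, l)``, which makes downstream tree
    construction reproducible.
    """
    idx_m = M.indices
    idx_n = N.indices
    s_m = scaled_positions[idx_m]
    s_n = scaled_positions[idx_n]
    diff = s_n[None, :, :] - s_m[:, None, :]          # (|M|, |N|, 3)
    mi = wrap_scaled(diff) @ box.B.T
    norms_sq = np.einsum("klx,klx->kl", mi, mi)
    flat = int(np.argmin(norms_sq))                    # first occurrence:
    k_local, l_local = divmod(flat, len(idx_n))        # lexicographic tie-break
    return ProximityResult(
        k=int(idx_m[k_local]),
        l=int(idx_n[l_local]),
        vector=mi[k_local, l_local],
        norm=float(np.sqrt(norms_sq[k_local, l_local])),
        scaled_vector=diff[k_local, l_local],
    )


def proximity_vector(M: MoleculeSpec, N: MoleculeSpec,
                     scaled_positions: np.ndarray, box: TriclinicBox,
                     measure: str, weights: CenterWeights,
                     ) -> tuple[np.ndarray, float]:
    """Scaled distance vector S_MN (from M to N) and its MI norm in nm.

    ``measure`` is ``"minpair"`` (nearest minimum-image atom pair) or
    ``"centers"`` (vector between molecular centers).  The returned
    scaled vector is unwrapped; its nearest-integer part is exactly the
    lattice displacement that makes the two molecules minimum-image
    adjacent.
    """
    if measure == "minpair":
        result = min_pair_distance(M, N, scaled_positions, box)
        return result.scaled_vector, result.norm
    if measure == "centers":
        S = center_distance(M, N, scaled_positions, weights)
        mi = wrap_scaled(S) @ box.B.T
        return S, float(np.linalg.norm(mi))
    raise ValueError(f"unknown proximity measure {measure!r}")
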