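"""Shared test utilities: brute-force oracles and tiny config builders."""

from __future__ import annotations

import numpy as np

from fixbox import AtomRecord, Configuration, make_box

# all integer lattice offsets in {-k..k}^3, for exhaustive image searches
def lattice_offsets(kmax: int) -> np.ndarray:
    axis = np.arange(-kmax, kmax + 1)
    return np.array(np.meshgrid(axis, axis, axis, indexing="ij")).reshape(3, -1).T


def mi_brute(s_ij, B, kmax: int = 3) -> np.ndarray:
    """Exhaustive minimum-image vector: min-norm B(s_ij + k) over images."""
    offsets = lattice_offsets(kmax)
    vectors = (np.asarray(s_ij, dtype=float) + offsets) @ np.asarray(B).T
    norms = np.einsum("kx,kx->k", vectors, vectors)
    return vectors[int(np.argmin(norms))]


def mi_brute_batch(S, B, kmax: int = 3) -> np.ndarray:
    """Vectorized :func:`mi_brute` for an (n, 3) batch sharing one box."""
    offsets = lattice_offsets(kmax)
    vectors = (np.asarray(S, dtype=float)[:, None, :] + offsets[None]) @ np.asarray(B).T
    norms = np.einsum("nkx,nkx->nk", vectors, vectors)
    best = norms.argmin(axis=1)
    return vectors[np.arange(len(vectors)), best]


def make_config(residues, box=None, positions=None, title="test"):
    """Build a Configuration from (resname, n_atoms) residue specs.

    Positions default to a spread-out line so molecules are distinct;
    pass an (N, 3) array for specific geometry.
    """
    if box is None:
        box = make_box((10.0, 0, 0), (0, 10.0, 0), (0, 0, 10.0))
    atoms = []
    serial = 0
    for residue_number, (resname, n_atoms) in enumerate(residues, start=1):
        for i in range(n_atoms):
            if positions is not None:
                pos = tuple(float(x) for x in positions[serial])
            else:
                pos = (0.01 * serial, 0.0, 0.0)
            serial += 1
            atoms.append(AtomRecord(
                residue_number=residue_number,
                residue_name=resname,
                atom_name=f"A{i+1}",
                atom_number=serial,
                position=pos,
            ))
    return Configuration(title=title, atoms=atoms, box=box)


CHART_STYLE_DEFS = """\
G Proteins
a 1 700
a 701 900
a 901 1000
G Bilayer
n BLU
G System
g Proteins
g Bilayer
A Proteins
A Bilayer
C Proteins Proteins System E E W
P Bilayer Bilayer None
"""


def chart_style_config():
    """1000 protein atoms in three chains plus five 3-atom BLU residues."""
    residues = [("CHA", 700), ("CHB", 200), ("CHC", 100)]
    residues += [("BLU", 3)] * 5
    return make_config(residues)
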