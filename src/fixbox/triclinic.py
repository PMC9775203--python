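"""Triclinic lattice geometry.

A periodic simulation cell is described by three linearly independent
*primitive vectors* ``b1, b2, b3`` (in nm).  Collected as the columns of
the box matrix ``B`` they generate the infinite lattice of replica boxes:
every lattice translation is ``B @ k`` for an integer triple ``k``.

All periodic bookkeeping in this package happens in *scaled* (reduced)
coordinates ``s = B^-1 (r - g)``, where ``g`` is the geometric center of
the reference box.  In scaled space the reference box is the unit cube
centered at the origin, so wrapping and minimum-image arithmetic reduce
to nearest-integer rounding, whatever the cell shape.

The nearest-integer convention used throughout is ``⌈a⌋ = floor(a + 1/2)``:
exact halves round toward +infinity (0.5 -> 1, -0.5 -> 0).  Wrapped scaled
coordinates therefore always lie in the half-open interval [-1/2, 1/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SingularBoxError

logger = logging.getLogger(__name__)

#: determinant magnitude (nm^3) below which a box is rejected as singular
SINGULAR_TOLERANCE = 1e-9

#: accepted spellings of the box-center convention
CENTER_CONVENTIONS = ("half-sum", "origin")


@dataclass
class TriclinicBox:
    """A parallelepipedic periodic cell.

    Attributes
    ----------
    B:
        3x3 box matrix; the primitive vectors are its *columns* (nm).
    Binv:
        Inverse of ``B``.
    g:
        Geometric center of the reference box (nm).  Either
        ``(b1+b2+b3)/2`` or the zero vector, depending on the convention
        used when the box was built.
    center_convention:
        Which of the two conventions ``g`` follows.
    """

    B: np.ndarray
    Binv: np.ndarray
    g: np.ndarray
    center_convention: str = "half-sum"

    @property
    def b1(self) -> np.ndarray:
        return self.B[:, 0]

    @property
    def b2(self) -> np.ndarray:
        return self.B[:, 1]

    @property
    def b3(self) -> np.ndarray:
        return self.B[:, 2]

    @property
    def volume(self) -> float:
        """Box volume in nm^3, ``|det B| = |b1 . (b2 x b3)|``."""
        return abs(float(np.linalg.det(self.B)))

    @property
    def handedness(self) -> int:
        """+1 for a right-handed primitive-vector set, -1 for left-handed."""
        return 1 if float(np.linalg.det(self.B)) > 0 else -1

    def min_primitive_length(self) -> float:
        return float(min(np.linalg.norm(self.B, axis=0)))


def make_box(b1, b2, b3, center_convention: str = "half-sum") -> TriclinicBox:
    """Build a :class:`TriclinicBox` from its primitive vectors.

    Raises
    ------
    SingularBoxError
        If ``|det B|`` is below :data:`SINGULAR_TOLERANCE` (coplanar
        vectors).
    ValueError
        For an unknown center convention.
    """
    if center_convention not in CENTER_CONVENTIONS:
        raise ValueError(
            f"unknown center convention {center_convention!r}; "
            f"expected one of {CENTER_CONVENTIONS}"
        )
    B = np.column_stack(
        [np.asarray(b, dtype=float).reshape(3) for b in (b1, b2, b3)]
    )
    det = float(np.linalg.det(B))
    if abs(det) < SINGULAR_TOLERANCE:
        raise SingularBoxError(
            f"primitive vectors are coplanar (|det B| = {abs(det):.3g} nm^3)"
        )
    if det < 0:
        # A left-handed set is legal, merely inconvenient; keep it.
        logger.warning(
            "primitive vectors form a left-handed set (b1.(b2 x b3) = %.6g nm^3)",
            det,
        )
    if center_convention == "half-sum":
        g = B.sum(axis=1) / 2.0
    else:
        g = np.zeros(3)
    return TriclinicBox(B=B, Binv=np.linalg.inv(B), g=g,
                        center_convention=center_convention)


def to_scaled(r, box: TriclinicBox) -> np.ndarray:
    """Map physical positions (nm) to scaled coordinates, ``s = B^-1 (r - g)``.

    Accepts a single 3-vector or an ``(..., 3)`` array.
    """
    r = np.asarray(r, dtype=float)
    return (r - box.g) @ box.Binv.T


def to_physical(s, box: TriclinicBox) -> np.ndarray:
    """Map scaled coordinates back to physical positions, ``r = B s + g``."""
    s = np.asarray(s, dtype=float)
    return s @ box.B.T + box.g


def nearest_int(a) -> np.ndarray:
    """Componentwise nearest integer, ``⌈a⌋ = floor(a + 1/2)``.

    Exact halves round toward +infinity: ``nearest_int(0.5) == 1`` and
    ``nearest_int(-0.5) == 0``.
    """
    a = np.asarray(a, dtype=float)
    return np.floor(a + 0.5).astype(np.int64)


def wrap_scaled(s) -> np.ndarray:
    """Wrap scaled coordinates into the reference box.

    Returns ``s° = s - ⌈s⌋``; every component of the result lies in
    [-1/2, 1/2), and ``s - s°`` is integer valued.
    """
    s = np.asarray(s, dtype=float)
    return s - np.floor(s + 0.5)


def mi_vector(s_ij, box: TriclinicBox) -> np.ndarray:
    """Minimum-image vector (nm) for a scaled free vector ``s_ij``.

    Computed as ``B (s_ij - ⌈s_ij⌋)``.  For a rectangular box this is the
    shortest of all lattice images of the vector.  For a skewed box it is
    guaranteed shortest only when the returned length is below half the
    shortest primitive vector; this package only uses it to rank
    candidate nearest pairs, for which the distinction is immaterial.
    """
    return wrap_scaled(s_ij) @ box.B.T
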