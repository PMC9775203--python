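"""Bounding-box centering of the assembled complex.

The bounding box is computed in scaled space from per-axis molecule
sets: along each axis the minimum and maximum scaled coordinate over the
atoms of that axis' centering set.  One rigid translation then moves the
bounding-box midpoint to the origin — the center of the reference box —
and is applied to *every* atom of the system.  Because the box mapping
is affine, a bounding box centered in scaled space is also centered in
physical space (parallel faces stay parallel and midpoints stay
midpoints), so no work is needed back in physical coordinates.

A centering set with scaled extent larger than 1 along an axis cannot
fit in the box along that axis; each axis carries a flag saying whether
that is an error, a warning, or ignorable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .defsfile import AXES, Flag, Group, Topology
from .errors import BoxExtentError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundingBox:
    """Per-axis extrema of the centering sets, in scaled coordinates."""

    s_min: np.ndarray
    s_max: np.ndarray

    @property
    def extent(self) -> np.ndarray:
        return self.s_max - self.s_min

    @property
    def midpoint(self) -> np.ndarray:
        return (self.s_min + self.s_max) / 2.0


@dataclass(frozen=True)
class FlagEvent:
    """One axis whose centering set is wider than the box."""

    axis: str
    severity: Flag
    extent: float


def bounding_box(centering_sets: tuple[Group, Group, Group],
                 topology: Topology,
                 scaled_positions: np.ndarray) -> BoundingBox:
    """Per-axis min/max of the scaled coordinates of each axis' set.

    Different axes may use different molecule sets (e.g. protein only in
    the membrane plane, protein plus bilayer normal to it).  An empty set
    leaves the axis without a bounding box and is an error.
    """
    s_min = np.empty(3)
    s_max = np.empty(3)
    for axis, group in enumerate(centering_sets):
        if len(group) == 0:
            raise ValueError(
                f"centering set along {AXES[axis]} ({group.name!r}) is empty"
            )
        indices = np.concatenate(
            [topology.by_id(m).indices for m in group.molecule_ids]
        )
        component = scaled_positions[indices, axis]
        s_min[axis] = component.min()
        s_max[axis] = component.max()
    return BoundingBox(s_min=s_min, s_max=s_max)


def center_translation(bbox: BoundingBox) -> np.ndarray:
    """The scaled translation that moves the bounding-box midpoint to 0."""
    return bbox.midpoint


def apply_centering(scaled_positions: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    """Rigidly translate *all* atoms by ``-translation`` in scaled space."""
    return scaled_positions - translation


def check_flags(bbox: BoundingBox, flags: tuple[Flag, Flag, Flag],
                snapshot: int | None = None) -> list[FlagEvent]:
    """Evaluate the per-axis extent flags.

    An extent strictly larger than 1 triggers the configured severity:
    ``E`` raises :class:`BoxExtentError`, ``W`` logs a warning, ``I`` is
    silent.  An extent of exactly 1 passes.  Returns the warn events.
    """
    events: list[FlagEvent] = []
    for axis, (flag, extent) in enumerate(zip(flags, bbox.extent)):
        if extent <= 1.0 or flag is Flag.IGNORE:
            continue
        if flag is Flag.ERROR:
            raise BoxExtentError(AXES[axis], float(extent), snapshot)
        events.append(FlagEvent(axis=AXES[axis], severity=flag,
                                extent=float(extent)))
        logger.warning(
            "centering set wider than the box along %s (scaled extent %.4f)",
            AXES[axis], extent,
        )
    return events
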