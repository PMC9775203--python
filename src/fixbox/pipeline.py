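"""The four-step fixing pipeline for one snapshot.

Coordinates are mapped to scaled space, the complex is reassembled by
integer lattice displacements along a nearest-neighbor tree, the
per-axis bounding box of the centering sets is translated to the box
center, remaining molecules are wrapped in by their centers, and the
result is mapped back to physical space.  The box itself is never
altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import AssemblyTree, assemble
from .centering import (BoundingBox, FlagEvent, apply_centering, bounding_box,
                        center_translation, check_flags)
from .defsfile import FixPlan
from .groio import Configuration
from .proximity import CenterWeights, WeightScheme
from .triclinic import to_scaled
from .wrapping import finalize, wrap_molecules


@dataclass
class FixResult:
    """The fixed snapshot plus everything decided along the way."""

    configuration: Configuration
    displacements: dict[int, np.ndarray]   # assembly K per molecule
    tree: AssemblyTree
    bbox: BoundingBox
    translation: np.ndarray                # scaled centering translation
    flag_events: list[FlagEvent]
    wrap_shifts: dict[int, np.ndarray]     # wrapping shifts per molecule


def fix_configuration(config: Configuration, plan: FixPlan,
                      measure: str = "minpair",
                      weight_scheme: WeightScheme = WeightScheme.GEOMETRIC,
                      seed_molecule: int | None = None,
                      snapshot: int | None = None) -> FixResult:
    """Run assembly, centering and wrapping on one snapshot.

    ``snapshot`` is only used to label flag errors when processing
    multi-snapshot inputs.  Each snapshot is fixed with its own box, so
    constant-pressure trajectories whose box breathes frame to frame are
    handled per frame.
    """
    box = config.box
    weights = CenterWeights(plan.topology, config.atoms, weight_scheme)
    s = to_scaled(config.positions, box)

    assembled = assemble(plan.assembly_stages, plan.topology, s, box,
                         measure=measure, weights=weights,
                         seed_molecule=seed_molecule)

    bbox = bounding_box(plan.centering_sets, plan.topology,
                        assembled.scaled_positions)
    events = check_flags(bbox, plan.centering_flags, snapshot)
    translation = center_translation(bbox)
    s_centered = apply_centering(assembled.scaled_positions, translation)

    s_wrapped, wrap_shifts = wrap_molecules(plan.wrapping_sets, plan.topology,
                                            s_centered, weights)

    positions = finalize(s_wrapped, box)
    return FixResult(
        configuration=config.with_positions(positions),
        displacements=assembled.displacements,
        tree=assembled.tree,
        bbox=bbox,
        translation=translation,
        flag_events=events,
        wrap_shifts=wrap_shifts,
    )
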