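"""Stage-wise reassembly of a molecular complex.

Each molecule of the complex is translated by an integer number of
boxes along each lattice direction, ``s_i' = s_i + K_M`` for atom i of
molecule M, so intramolecular geometry is untouched.  The displacements
are chosen greedily: starting from a seed molecule with ``K = 0``, the
closest (by minimum-image proximity) pair of one unassembled and one
assembled molecule is linked, the newcomer inheriting

    K_M = K_N + round(S_MN)

from its parent N, where S_MN is the scaled proximity vector from M to N
measured on the original coordinates.  Requiring this relation for every
pair at once is impossible in general (rounding is not additive), so it
is enforced only along the links actually chosen; the links form a tree
whose induced relative arrangement does not depend on the seed.

Assembly can run in several disjoint stages: the molecules of stage 2
attach to the already assembled stage-1 set, and so on.  This lets a
multi-subunit protein be made whole before the surrounding lipids, whose
mutual nearest-neighbor chains could otherwise drag subunits into
different lattice images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .defsfile import Group, Topology
from .proximity import CenterWeights, proximity_vector
from .triclinic import TriclinicBox, nearest_int

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Edge:
    """A tree link: ``child`` was attached to the already-assembled ``parent``."""

    child: int
    parent: int
    norm: float


@dataclass
class AssemblyTree:
    """The nearest-neighbor tree built during assembly."""

    seed: int
    edges: list[Edge] = field(default_factory=list)
    stage_index: dict[int, int] = field(default_factory=dict)

    def parents(self) -> dict[int, int]:
        return {e.child: e.parent for e in self.edges}


@dataclass
class AssemblyResult:
    scaled_positions: np.ndarray            # s' for every atom
    displacements: dict[int, np.ndarray]    # molecule id -> integer K
    tree: AssemblyTree


def assemble(stages: list[Group], topology: Topology,
             scaled_positions: np.ndarray, box: TriclinicBox,
             measure: str = "minpair",
             weights: CenterWeights | None = None,
             seed_molecule: int | None = None) -> AssemblyResult:
    """Assemble the staged molecule sets; all other atoms stay put.

    ``seed_molecule`` overrides the default seed (the lowest molecule id
    of the first non-empty stage); the choice only shifts the whole
    assembled complex by a global lattice vector, which the centering
    step removes.  Ties in the greedy pair selection are broken by the
    lowest ``(child id, parent id)``.
    """
    if weights is None:
        weights = CenterWeights(topology)
    K: dict[int, np.ndarray] = {}
    marked: list[int] = []
    tree: AssemblyTree | None = None
    # best known link per unassembled molecule: id -> (norm, parent, S_raw)
    best: dict[int, tuple[float, int, np.ndarray]] = {}

    def link(child: int, parent: int) -> tuple[float, np.ndarray]:
        S, norm = proximity_vector(
            topology.by_id(child), topology.by_id(parent),
            scaled_positions, box, measure, weights,
        )
        return norm, S

    for stage_number, stage in enumerate(stages, start=1):
        todo = list(dict.fromkeys(stage.molecule_ids))
        if not todo:
            logger.warning("assembly stage %d (%s) is empty; skipping",
                           stage_number, stage.name)
            continue
        if not marked:
            seed = seed_molecule if seed_molecule is not None else min(todo)
            if seed not in todo:
                raise ValueError(
                    f"seed molecule {seed} is not in the first assembly stage"
                )
            K[seed] = np.zeros(3, dtype=np.int64)
            marked.append(seed)
            tree = AssemblyTree(seed=seed)
            tree.stage_index[seed] = stage_number
            todo.remove(seed)
        assert tree is not None
        for child in todo:
            candidates = [(*link(child, parent), parent) for parent in marked]
            norm, S, parent = min(candidates, key=lambda c: (c[0], c[2]))
            best[child] = (norm, parent, S)
        todo_set = set(todo)
        while todo_set:
            child = min(todo_set, key=lambda m: (best[m][0], m, best[m][1]))
            norm, parent, S = best[child]
            K[child] = K[parent] + nearest_int(S)
            tree.edges.append(Edge(child=child, parent=parent, norm=norm))
            tree.stage_index[child] = stage_number
            todo_set.remove(child)
            marked.append(child)
            del best[child]
            for other in todo_set:
                norm, S = link(other, child)
                if (norm, child) < (best[other][0], best[other][1]):
                    best[other] = (norm, child, S)
        logger.info("assembled stage %d (%s): %d molecules",
                    stage_number, stage.name, len(stage.molecule_ids))

    s_new = np.array(scaled_positions, dtype=float, copy=True)
    for molecule_id, displacement in K.items():
        s_new[topology.by_id(molecule_id).indices] += displacement
    if tree is None:
        tree = AssemblyTree(seed=0)
        logger.warning("no molecules assembled (all stages empty)")
    return AssemblyResult(scaled_positions=s_new, displacements=K, tree=tree)
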