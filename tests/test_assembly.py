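"""Tree-based complex assembly: seeds, displacements, staging."""

import numpy as np
import pytest

from fixbox import (CenterWeights, FixtureSpec, Group, Topology, assemble,
                    fix_configuration, generate, make_box, nearest_int,
                    parse_definitions, proximity_vector, to_scaled)


def point_molecules(*scaled_points):
    """One single-atom molecule per point; returns (topology, scaled array)."""
    top = Topology(len(scaled_points))
    for serial in range(1, len(scaled_points) + 1):
        top.add_molecule((serial,))
    return top, np.asarray(scaled_points, dtype=float)


UNIT_BOX = make_box((1, 0, 0), (0, 1, 0), (0, 0, 1))


class TestSingleStage:
    def test_lone_molecule_gets_zero_displacement(self):
        top, s = point_molecules((0.3, 0.1, -0.2))
        result = assemble([Group("A", (1,))], top, s, UNIT_BOX)
        assert np.array_equal(result.displacements[1], (0, 0, 0))
        assert result.tree.seed == 1 and result.tree.edges == []

    def test_two_molecules_across_the_box(self):
        # rounding the scaled separation of 0.6 gives one box: the child
        # is displaced by -1 along x to sit minimum-image beside the seed
        top, s = point_molecules((-0.3, 0, 0), (0.3, 0, 0))
        result = assemble([Group("A", (1, 2))], top, s, UNIT_BOX)
        assert np.array_equal(result.displacements[1], (0, 0, 0))
        assert np.array_equal(result.displacements[2], (-1, 0, 0))
        s_new = result.scaled_positions
        assert np.allclose(s_new[1], (-0.7, 0, 0))

    def test_collinear_triple_cannot_satisfy_all_pairs(self):
        # rounding is not additive: round(S_MN) != round(S_MP) + round(S_PN)
        # for molecules at -0.3, 0, +0.3 — the tree only honors its edges
        top, s = point_molecules((-0.3, 0, 0), (0, 0, 0), (0.3, 0, 0))
        S_MN = s[2] - s[0]
        S_MP = s[1] - s[0]
        S_PN = s[2] - s[1]
        assert tuple(nearest_int(S_MN)) == (1, 0, 0)
        assert tuple(nearest_int(S_MP) + nearest_int(S_PN)) == (0, 0, 0)
        result = assemble([Group("A", (1, 2, 3))], top, s, UNIT_BOX)
        s_new = result.scaled_positions
        # every tree edge is minimum-image satisfied after displacement
        for edge in result.tree.edges:
            gap = s_new[edge.parent - 1] - s_new[edge.child - 1]
            assert np.array_equal(nearest_int(gap), (0, 0, 0))

    def test_edges_connect_unmarked_to_marked_in_greedy_order(self):
        rng = np.random.default_rng(8)
        top, s = point_molecules(*rng.uniform(-0.5, 0.5, (12, 3)))
        result = assemble([Group("A", tuple(range(1, 13)))], top, s, UNIT_BOX)
        marked = {result.tree.seed}
        for edge in result.tree.edges:
            assert edge.parent in marked and edge.child not in marked
            marked.add(edge.child)
        assert marked == set(range(1, 13))


class TestDisplacementBookkeeping:
    def test_pairwise_consistency_after_displacement(self):
        # S'_MN = S_MN + K_N - K_M for every assembled pair
        broken, _, defs = generate(FixtureSpec("micelle", seed=7))
        plan = parse_definitions(defs, broken)
        top = plan.topology
        weights = CenterWeights(top)
        s = to_scaled(broken.positions, broken.box)
        result = assemble(plan.assembly_stages, top, s, broken.box)
        ids = plan.assembly_stages[0].molecule_ids
        for M in ids[:4]:
            for N in ids[:4]:
                if M == N:
                    continue
                S, _ = proximity_vector(top.by_id(M), top.by_id(N), s,
                                        broken.box, "minpair", weights)
                S_new, _ = proximity_vector(top.by_id(M), top.by_id(N),
                                            result.scaled_positions,
                                            broken.box, "minpair", weights)
                expected = (S + result.displacements[N]
                            - result.displacements[M])
                assert np.allclose(S_new, expected, atol=1e-12)

    def test_displaced_parent_formulation_is_equivalent(self):
        # computing K from the parent's already-displaced coordinates and
        # rounding once gives the same integer as the K_N bookkeeping
        broken, _, defs = generate(FixtureSpec("membrane_peptide", seed=2))
        plan = parse_definitions(defs, broken)
        top = plan.topology
        weights = CenterWeights(top)
        s = to_scaled(broken.positions, broken.box)
        result = assemble(plan.assembly_stages, top, s, broken.box)
        for edge in result.tree.edges[:25]:
            s_mixed = s.copy()
            parent = top.by_id(edge.parent)
            s_mixed[parent.indices] += result.displacements[edge.parent]
            S, _ = proximity_vector(top.by_id(edge.child), parent, s_mixed,
                                    broken.box, "minpair", weights)
            assert np.array_equal(nearest_int(S),
                                  result.displacements[edge.child])

    def test_atoms_move_by_exact_lattice_vectors_only(self):
        broken, _, defs = generate(FixtureSpec("dimer", seed=5))
        plan = parse_definitions(defs, broken)
        s = to_scaled(broken.positions, broken.box)
        result = assemble(plan.assembly_stages, plan.topology, s, broken.box)
        moved = result.scaled_positions - s
        for molecule in plan.topology.molecules:
            d = moved[molecule.indices]
            expected = result.displacements.get(molecule.molecule_id,
                                                np.zeros(3))
            assert np.array_equal(d, np.tile(expected, (len(d), 1)))


class TestStaging:
    def test_later_stage_attaches_to_all_prior_marked(self):
        broken, _, defs = generate(FixtureSpec("membrane_peptide", seed=1))
        plan = parse_definitions(defs, broken)
        s = to_scaled(broken.positions, broken.box)
        result = assemble(plan.assembly_stages, plan.topology, s, broken.box)
        stage2 = set(plan.assembly_stages[1].molecule_ids)
        first_stage2_edge = next(e for e in result.tree.edges
                                 if e.child in stage2)
        # the first lipid hooks onto the stage-1 peptide, not onto a lipid
        assert first_stage2_edge.parent in \
            set(plan.assembly_stages[0].molecule_ids)

    def test_empty_stage_warns_and_continues(self, caplog):
        top, s = point_molecules((0.1, 0, 0), (0.2, 0, 0))
        with caplog.at_level("WARNING", logger="fixbox.assembly"):
            result = assemble(
                [Group("A", (1, 2)), Group("Empty", ())], top, s, UNIT_BOX)
        assert len(result.displacements) == 2
        assert any("empty" in r.message for r in caplog.records)

    def test_seed_outside_first_stage_rejected(self):
        top, s = point_molecules((0.1, 0, 0), (0.2, 0, 0), (0.3, 0, 0))
        with pytest.raises(ValueError, match="first assembly stage"):
            assemble([Group("A", (1, 2))], top, s, UNIT_BOX, seed_molecule=3)


class TestStartIndependence:
    @pytest.mark.parametrize("kind", ["dimer", "micelle"])
    def test_any_seed_gives_same_centered_configuration(self, kind):
        broken, _, defs = generate(FixtureSpec(kind, seed=11))
        plan = parse_definitions(defs, broken)
        stage1 = plan.assembly_stages[0].molecule_ids
        reference = None
        for seed_molecule in stage1:
            result = fix_configuration(broken, plan,
                                       seed_molecule=int(seed_molecule))
            positions = result.configuration.positions
            if reference is None:
                reference = positions
            else:
                assert np.abs(positions - reference).max() < 1e-9
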