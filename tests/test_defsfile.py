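"""Definitions-file parsing: groups, stages, centering/wrapping lines."""

import pytest

from fixbox import DefsError, Flag, parse_definitions, resolve_residue_molecules
from helpers import CHART_STYLE_DEFS, chart_style_config, make_config


@pytest.fixture
def chart_plan():
    return parse_definitions(CHART_STYLE_DEFS, chart_style_config())


class TestChartStyleParse:
    def test_two_assembly_stages_in_order(self, chart_plan):
        assert [s.name for s in chart_plan.assembly_stages] == \
            ["Proteins", "Bilayer"]

    def test_proteins_group_molecules_and_serials(self, chart_plan):
        proteins = chart_plan.groups["Proteins"]
        assert len(proteins) == 3
        top = chart_plan.topology
        serials = [s for m in proteins.molecule_ids
                   for s in top.by_id(m).atom_serials]
        assert max(serials) == 1000
        assert top.by_id(proteins.molecule_ids[0]).atom_serials[:2] == (1, 2)

    def test_centering_sets_and_flags(self, chart_plan):
        names = [g.name for g in chart_plan.centering_sets]
        assert names == ["Proteins", "Proteins", "System"]
        assert chart_plan.centering_flags == (Flag.ERROR, Flag.ERROR, Flag.WARN)

    def test_z_wrapping_set_is_empty(self, chart_plan):
        assert [g.name for g in chart_plan.wrapping_sets] == \
            ["Bilayer", "Bilayer", "None"]
        assert len(chart_plan.wrapping_sets[2]) == 0

    def test_bilayer_resolved_per_residue(self, chart_plan):
        bilayer = chart_plan.groups["Bilayer"]
        assert len(bilayer) == 5
        assert all(
            len(chart_plan.topology.by_id(m).atom_serials) == 3
            for m in bilayer.molecule_ids
        )


class TestResidueResolution:
    def test_one_molecule_per_residue_run(self):
        config = make_config([("SOL", 3)] * 3 + [("ION", 1)])
        runs = resolve_residue_molecules(config, "SOL")
        assert runs == [(1, 2, 3), (4, 5, 6), (7, 8, 9)]

    def test_absent_residue_warns_and_is_empty(self, caplog):
        config = make_config([("SOL", 3)])
        with caplog.at_level("WARNING", logger="fixbox.defsfile"):
            runs = resolve_residue_molecules(config, "XYZ")
        assert runs == []
        assert any("XYZ" in r.message for r in caplog.records)

    def test_wrapped_residue_numbering_still_splits_runs(self):
        # same residue number repeated back-to-back (numbering wrapped
        # modulo 100000) must still split at each run boundary
        config = make_config([("SOL", 2)] * 4)
        for atom in config.atoms:
            atom.residue_number = 1 if atom.residue_number in (1, 3) else 2
        runs = resolve_residue_molecules(config, "SOL")
        assert runs == [(1, 2), (3, 4), (5, 6), (7, 8)]


class TestValidation:
    def test_undefined_group_reference(self):
        text = "G A\na 1 3\nG B\ng Nope\nA A\nC A A A\nP A A A\n"
        with pytest.raises(DefsError, match="undefined group 'Nope'"):
            parse_definitions(text, make_config([("X", 10)]))

    def test_duplicate_group_definition(self):
        text = "G A\na 1 3\nG A\na 4 6\nA A\nC A A A\nP A A A\n"
        with pytest.raises(DefsError, match="defined twice"):
            parse_definitions(text, make_config([("X", 10)]))

    def test_overlapping_atom_ranges(self):
        text = "G A\na 1 5\na 4 8\nA A\nC A A A\nP A A A\n"
        with pytest.raises(DefsError, match="already belongs"):
            parse_definitions(text, make_config([("X", 10)]))

    def test_identical_range_reuses_molecule(self):
        text = ("G A\na 1 5\nG B\na 1 5\nA A\n"
                "C A A A\nP B B B\n")
        plan = parse_definitions(text, make_config([("X", 10)]))
        assert plan.groups["A"].molecule_ids == plan.groups["B"].molecule_ids

    def test_overlapping_stages_rejected(self):
        text = "G A\na 1 5\nG B\ng A\nA A\nA B\nC A A A\nP A A A\n"
        with pytest.raises(DefsError, match="stages overlap"):
            parse_definitions(text, make_config([("X", 10)]))

    @pytest.mark.parametrize("drop, missing", [("C", "C line"), ("P", "P line")])
    def test_missing_mandatory_line(self, drop, missing):
        lines = [l for l in "G A\na 1 5\nA A\nC A A A\nP A A A".splitlines()
                 if not l.startswith(drop)]
        with pytest.raises(DefsError, match=missing):
            parse_definitions("\n".join(lines), make_config([("X", 10)]))

    def test_duplicate_c_line(self):
        text = "G A\na 1 5\nA A\nC A A A\nC A A A\nP A A A\n"
        with pytest.raises(DefsError, match="duplicate C"):
            parse_definitions(text, make_config([("X", 10)]))

    def test_unknown_key_and_flag(self):
        with pytest.raises(DefsError, match="unknown line key"):
            parse_definitions("Q wat\n", make_config([("X", 5)]))
        text = "G A\na 1 5\nA A\nC A A A E E Q\nP A A A\n"
        with pytest.raises(DefsError, match="unknown centering flag"):
            parse_definitions(text, make_config([("X", 10)]))

    def test_reserved_name_none(self):
        with pytest.raises(DefsError, match="reserved"):
            parse_definitions("G None\na 1 2\n", make_config([("X", 5)]))

    def test_atom_serial_out_of_bounds(self):
        text = "G A\na 1 99\nA A\nC A A A\nP A A A\n"
        with pytest.raises(DefsError, match="outside 1..10"):
            parse_definitions(text, make_config([("X", 10)]))


class TestConveniences:
    def test_comments_blank_lines_and_whitespace_ignored(self):
        text = ("# header\n\nG A  \n  a 1 5\n\n# mid\nA A\n"
                "C A A A W W W  \nP A A A\n")
        plan = parse_definitions(text, make_config([("X", 10)]))
        assert len(plan.groups["A"]) == 1

    def test_flags_default_to_warn(self):
        text = "G A\na 1 5\nA A\nC A A A\nP A A A\n"
        plan = parse_definitions(text, make_config([("X", 10)]))
        assert plan.centering_flags == (Flag.WARN,) * 3

    def test_ignore_flag_accepted(self):
        text = "G A\na 1 5\nA A\nC A A A I W E\nP A A A\n"
        plan = parse_definitions(text, make_config([("X", 10)]))
        assert plan.centering_flags == (Flag.IGNORE, Flag.WARN, Flag.ERROR)

    def test_builtin_system_covers_all_molecules(self):
        text = "G A\na 1 5\nG B\nn SOL\nA A\nC A A A\nP System System System\n"
        config = make_config([("X", 5), ("SOL", 3), ("SOL", 3)])
        plan = parse_definitions(text, config)
        assert len(plan.wrapping_sets[0]) == 3

    def test_parse_is_deterministic(self):
        config = chart_style_config()
        a = parse_definitions(CHART_STYLE_DEFS, config)
        b = parse_definitions(CHART_STYLE_DEFS, config)
        assert [g.molecule_ids for g in a.assembly_stages] == \
            [g.molecule_ids for g in b.assembly_stages]
        assert a.centering_flags == b.centering_flags
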