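"""Hybrid dual-state residue construction, cross terms, and the topology dialect."""

import dataclasses
import itertools

import pytest

from dsbredox.topology import (
    DUMMY_TYPE,
    HUD,
    VSITE_CB,
    VSITE_S,
    AtomState,
    BondedTerms,
    HybridAtom,
    ResidueTemplate,
    TemplateAtom,
    TopologyError,
    build_hybrid_residue,
    pair_cross_terms,
    project_state,
    read_perturbed_topology,
    read_residue_template,
    validate_state_equivalence,
    write_perturbed_topology,
    write_residue_template,
)


@pytest.fixture()
def hybrid(cys2_template, cys_template):
    return build_hybrid_residue(cys2_template, cys_template)


def _toy_templates():
    """Minimal 6-atom reduced vs 5-atom oxidized template pair."""
    red = ResidueTemplate(
        name="RED",
        atoms=(
            TemplateAtom("N", "NH1", -0.3, 14.007),
            TemplateAtom("CA", "CT1", 0.2, 12.011),
            TemplateAtom("CB", "CT2", -0.1, 12.011),
            TemplateAtom("SG", "S", -0.2, 32.06),
            TemplateAtom("HG1", "HS", 0.15, 1.008),
            TemplateAtom("C", "C", 0.25, 12.011),
        ),
        bonds=(("N", "CA"), ("CA", "CB"), ("CB", "SG"), ("SG", "HG1"), ("CA", "C")),
        formal_charge=0.0,
    )
    ox = ResidueTemplate(
        name="OX",
        atoms=(
            TemplateAtom("N", "NH1", -0.3, 14.007),
            TemplateAtom("CA", "CT1", 0.2, 12.011),
            TemplateAtom("CB", "CT2", -0.05, 12.011),
            TemplateAtom("SG", "S", -0.1, 32.06),
            TemplateAtom("C", "C", 0.25, 12.011),
        ),
        bonds=(("N", "CA"), ("CA", "CB"), ("CB", "SG"), ("CA", "C")),
        formal_charge=0.0,
    )
    return ox, red


class TestTemplates:
    def test_charge_sum_must_match_declared(self):
        with pytest.raises(TopologyError, match="charge sum"):
            ResidueTemplate(
                name="BAD",
                atoms=(TemplateAtom("A", "X", 0.5, 1.0),),
                formal_charge=0.0,
            )

    def test_bonded_terms_must_reference_known_atoms(self):
        with pytest.raises(TopologyError, match="unknown"):
            ResidueTemplate(
                name="BAD",
                atoms=(TemplateAtom("A", "X", 0.0, 1.0),),
                bonds=(("A", "Z"),),
            )

    def test_file_round_trip(self, tmp_path, cys_template):
        p = tmp_path / "cys.rtp"
        write_residue_template(cys_template, p)
        assert read_residue_template(p) == cys_template


class TestBuildHybrid:
    def test_atom_count_is_reduced_plus_two_virtual_sites(self):
        ox, red = _toy_templates()
        h = build_hybrid_residue(ox, red)
        assert len(h.atoms) == len(red.atoms) + 2

    def test_a_state_projection_equals_oxidized_template(self, hybrid, cys2_template):
        assert project_state(hybrid, "A", name=cys2_template.name) == cys2_template

    def test_b_state_projection_equals_reduced_template(self, hybrid, cys_template):
        assert project_state(hybrid, "B", name=cys_template.name) == cys_template

    def test_b_state_charge_sum_matches_reduced_template(self, hybrid, cys_template):
        total = sum(
            a.b.charge for a in hybrid.atoms if not a.b.is_virtual_site
        )
        assert total == pytest.approx(cys_template.formal_charge, abs=1e-6)

    def test_hud_is_neutral_noninteracting_in_a_state(self, hybrid):
        hud = hybrid.atom(HUD)
        assert hud.a.charge == 0.0
        assert hud.a.type_label == DUMMY_TYPE
        assert hud.a.is_dummy

    def test_virtual_sites_anchor_cb_and_sulfur(self, hybrid):
        assert hybrid.atom(VSITE_CB).position_rule == "CB"
        assert hybrid.atom(VSITE_S).position_rule == "SG"
        for vname in (VSITE_CB, VSITE_S):
            v = hybrid.atom(vname)
            assert v.a.charge == v.b.charge == 0.0
            assert v.a.type_label == v.b.type_label == DUMMY_TYPE

    def test_atom_name_mismatch_is_structured_error(self, cys_template):
        bad_ox = ResidueTemplate(
            name="OX",
            atoms=(TemplateAtom("XX", "X", 0.0, 1.0), TemplateAtom("SG", "S", 0.0, 32.06)),
            bonds=(("XX", "SG"),),
        )
        with pytest.raises(TopologyError, match="only-in-oxidized.*XX"):
            build_hybrid_residue(bad_ox, cys_template)


class TestCrossTerms:
    def test_bond_and_two_angles(self, hybrid):
        ct = pair_cross_terms(hybrid, hybrid)
        assert ct.bond == ("1:SG", "2:SG")
        assert len(ct.angles) == 2
        assert set(ct.angles) == {("1:CB", "1:SG", "2:SG"), ("2:CB", "2:SG", "1:SG")}

    def test_b_state_terms_empty(self, hybrid):
        ct = pair_cross_terms(hybrid, hybrid)
        assert ct.terms_for_state("B") == BondedTerms()
        assert ct.terms_for_state("A").bonds == (("1:SG", "2:SG"),)

    def test_dihedrals_match_brute_force_path_search(self, hybrid):
        ct = pair_cross_terms(hybrid, hybrid)
        # oracle: every 4-atom simple path X-S1-S2-Y on the combined A-state
        # bond graph of the pair plus the S1-S2 bond
        edges = set()
        for prefix, res in (("1", hybrid), ("2", hybrid)):
            for a, b in res.bonded_a.bonds:
                edges.add(frozenset((f"{prefix}:{a}", f"{prefix}:{b}")))
        s1, s2 = "1:SG", "2:SG"
        edges.add(frozenset((s1, s2)))
        nodes = {n for e in edges for n in e}
        nbrs = {
            n: {m for m in nodes if frozenset((n, m)) in edges} for n in nodes
        }
        expected = set()
        for x in nbrs[s1] - {s2}:
            for y in nbrs[s2] - {s1}:
                if x != y:
                    t = (x, s1, s2, y)
                    expected.add(min(t, t[::-1]))
        assert {min(d, d[::-1]) for d in ct.dihedrals} == expected

    def test_non_cyd_input_rejected(self, cys2_template, cys_template):
        h = build_hybrid_residue(cys2_template, cys_template, name="XYZ")
        with pytest.raises(TopologyError, match="CYD"):
            pair_cross_terms(h, h)


class TestPerturbedTopologyFile:
    def test_round_trip_identity(self, tmp_path, hybrid):
        ct = pair_cross_terms(hybrid, hybrid)
        p = tmp_path / "top.itp"
        write_perturbed_topology([hybrid, hybrid], [ct], p)
        residues, cross = read_perturbed_topology(p)
        assert residues == [hybrid, hybrid]
        assert cross == [ct]

    def test_a_only_terms_carry_a_state_column(self, tmp_path, hybrid):
        p = tmp_path / "top.itp"
        write_perturbed_topology([hybrid], [], p)
        text = p.read_text()
        # the thiol-hydrogen bond exists only at lambda=1 (B); the writer
        # must not give it A-state parameters
        assert any(
            line.split()[:3] == ["HUD", "SG", "B"] or line.split()[:3] == ["SG", "HUD", "B"]
            for line in text.splitlines()
        )

    def test_golden_file_is_stable(self, tmp_path, hybrid):
        import pathlib

        golden = pathlib.Path(__file__).parent / "data" / "cyd_golden.itp"
        ct = pair_cross_terms(hybrid, hybrid)
        p = tmp_path / "top.itp"
        write_perturbed_topology([hybrid, hybrid], [ct], p)
        assert p.read_text() == golden.read_text()


class TestValidation:
    def test_correct_hybrid_passes(self, hybrid, cys2_template, cys_template):
        report = validate_state_equivalence(hybrid, cys2_template, cys_template)
        assert report.passed, [i for i in report.items if not i.passed]

    def test_charged_hud_fails(self, hybrid, cys2_template, cys_template):
        mutated = _mutate_atom(hybrid, HUD, a=dataclasses.replace(
            hybrid.atom(HUD).a, charge=0.1))
        report = validate_state_equivalence(mutated, cys2_template, cys_template)
        failed = [i.check for i in report.items if not i.passed]
        assert failed == ["HUD_A_state_neutral_dummy"]

    def test_fail_count_equals_injected_mutations(self, hybrid, cys2_template, cys_template):
        # three disjoint mutations -> exactly three failed checks
        mutated = _mutate_atom(hybrid, HUD, a=dataclasses.replace(
            hybrid.atom(HUD).a, charge=0.1))
        mutated = _mutate_atom(mutated, VSITE_CB, b=dataclasses.replace(
            mutated.atom(VSITE_CB).b, charge=-0.05))
        mutated = dataclasses.replace(mutated, cb_name="CA")
        report = validate_state_equivalence(mutated, cys2_template, cys_template)
        assert report.n_failed == 3


def _mutate_atom(hybrid, name, **fields):
    atoms = tuple(
        dataclasses.replace(a, **fields) if a.name == name else a
        for a in hybrid.atoms
    )
    return dataclasses.replace(hybrid, atoms=atoms)
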