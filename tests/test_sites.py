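"""Functional-site annotation: contacts, inheritance, interfaces, registries,
PTM validation and the SIFT/PolyPhen rule."""

import numpy as np
import pytest

from gpcrvar.numbering import GenericPosition, parse_generic_position
from gpcrvar.sites import (
    ContactRecord,
    FunctionalSiteAnnotation,
    MICROSWITCH_POSITIONS,
    PTMRecord,
    SODIUM_POCKET_POSITIONS,
    annotate_variant_sites,
    build_effector_interface,
    builtin_class_a_registries,
    contacts_from_structure,
    extract_ligand_binding_sites,
    inherit_family_sites,
    is_putative_functional,
    read_annotations_tsv,
    validate_ptm_sites,
    write_annotations_tsv,
)
from gpcrvar.variants import MissenseVariant

from conftest import make_toy_segment_map


def _contact(residue_index, distance, partner="ligand"):
    return ContactRecord("S1", "R1", residue_index, partner, distance)


class TestLigandBindingSites:
    def test_cutoff_boundary(self, toy_segment_map):
        tm1_start = toy_segment_map.ranges["TM1"][0]
        included = extract_ligand_binding_sites(
            [_contact(tm1_start, 4.4)], toy_segment_map
        )
        assert included == {GenericPosition("1", 48)}
        excluded = extract_ligand_binding_sites(
            [_contact(tm1_start, 4.6)], toy_segment_map
        )
        assert excluded == set()

    def test_residue_without_generic_number_excluded(self, toy_segment_map):
        # residue 1 is in the N-terminus, no generic position
        assert extract_ligand_binding_sites([_contact(1, 3.0)], toy_segment_map) == set()

    def test_monotone_in_cutoff(self, toy_segment_map):
        rng = np.random.default_rng(3)
        contacts = [
            _contact(int(i), float(d))
            for i, d in zip(
                rng.integers(1, toy_segment_map.length + 1, size=40),
                rng.uniform(2.0, 8.0, size=40),
            )
        ]
        prev = set()
        for cutoff in (3.0, 4.5, 6.0, 8.0):
            cur = extract_ligand_binding_sites(contacts, toy_segment_map, cutoff=cutoff)
            assert prev <= cur
            prev = cur


def _write_toy_pdb(path, receptor_xyz, ligand_xyz):
    """Three CA-only residues in chain A plus a HETATM ligand."""
    lines = []
    serial = 1
    for i, (x, y, z) in enumerate(receptor_xyz, start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    for j, (x, y, z) in enumerate(ligand_xyz, start=1):
        lines.append(
            f"HETATM{serial:5d}  C{j:<2d} LIG A 900    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def test_structure_contacts_match_brute_force_oracle(tmp_path):
    """Distances from the structure reader equal an independent all-atom scan."""
    receptor_xyz = [(0.0, 0.0, 0.0), (4.4, 0.0, 0.0), (10.0, 0.0, 0.0)]
    ligand_xyz = [(0.0, 0.0, 3.0), (8.0, 0.0, 0.0)]
    pdb = tmp_path / "toy.pdb"
    _write_toy_pdb(pdb, receptor_xyz, ligand_xyz)
    contacts = contacts_from_structure(pdb, receptor="R1", receptor_chain="A")
    got = {c.residue_index: c.min_distance for c in contacts}
    rx = np.array(receptor_xyz)
    lx = np.array(ligand_xyz)
    expected = np.sqrt(((rx[:, None, :] - lx[None, :, :]) ** 2).sum(-1)).min(axis=1)
    assert set(got) == {1, 2, 3}
    for i, exp in enumerate(expected, start=1):
        assert got[i] == pytest.approx(exp, abs=1e-6)
    # residue 1 is 3.0 A from the ligand -> inside 4.5; residue 3 is 2.0 -> inside;
    # residue 2 is 3.6 -> inside; shrink the cutoff to separate them
    within = {c.residue_index for c in contacts if c.min_distance <= 2.5}
    assert within == {3}


class TestFamilyInheritance:
    def test_sibling_inherits_shared_positions(self, toy_segment_map):
        donor_sites = {GenericPosition("3", 50), GenericPosition("5", 48)}
        member = make_toy_segment_map("R2")
        out = inherit_family_sites(donor_sites, member)
        assert {(p.segment_label, p.index) for p in out} == {("3", 50), ("5", 48)}

    def test_member_lacking_position_skips_it(self):
        member = make_toy_segment_map("R2")
        donor_sites = {GenericPosition("4", 55)}  # member only has x48..x52
        assert inherit_family_sites(donor_sites, member) == set()

    def test_ortholog_requires_identical_human_residue(self):
        donor = make_toy_segment_map("Rdog")
        member = make_toy_segment_map("Rhum")
        pos = GenericPosition("3", 50)
        idx = member.residue_of(pos)
        human_seq_match = donor.sequence  # same sequence -> identical residue
        assert inherit_family_sites(
            {pos}, member, donor_map=donor, donor_is_ortholog=True,
            human_sequence=human_seq_match,
        ) == {pos}
        mismatched = list(donor.sequence)
        mismatched[idx - 1] = "W" if mismatched[idx - 1] != "W" else "M"
        assert inherit_family_sites(
            {pos}, member, donor_map=donor, donor_is_ortholog=True,
            human_sequence="".join(mismatched),
        ) == set()


class TestEffectorInterface:
    def test_union_over_structures(self):
        sets = {
            "S1": {GenericPosition("3", 50), GenericPosition("5", 61)},
            "S2": {GenericPosition("3", 50), GenericPosition("6", 33)},
        }
        out = build_effector_interface(sets, "A")
        assert out == sets["S1"] | sets["S2"]

    def test_class_c_is_translated_union_of_a_and_b(self):
        a_sets = {"SA": {GenericPosition("3", 50, receptor_class="A")}}
        b_sets = {"SB": {GenericPosition("5", 50, receptor_class="B")}}
        out = build_effector_interface(
            {}, "C", class_a_sets=a_sets, class_b_sets=b_sets
        )
        keys = {(p.segment_label, p.index) for p in out}
        # A 3x50 → C 3x54 (offset +4); B 5x50 → A 5x54 → C 5x54 (A→C TM5 offset 0)
        assert keys == {("3", 54), ("5", 54)}
        assert all(p.receptor_class == "C" for p in out)

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            build_effector_interface({}, "Z")


class TestRegistries:
    def test_sodium_pocket_has_15_positions(self):
        _, sodium = builtin_class_a_registries("A")
        assert len(sodium) == 15
        assert sodium == SODIUM_POCKET_POSITIONS

    def test_microswitches_contain_3x50(self):
        micro, _ = builtin_class_a_registries("A")
        assert parse_generic_position("3x50", "A") in micro
        assert len(micro) == 17

    @pytest.mark.parametrize("rclass", ["B", "C", "F"])
    def test_non_class_a_queries_empty(self, rclass):
        micro, sodium = builtin_class_a_registries(rclass)
        assert micro == frozenset() and sodium == frozenset()


class TestPTMValidation:
    def test_kept_dropped_deduplicated(self):
        seqs = {"R1": "MASTR"}
        records = [
            PTMRecord("R1", 3, "S", "phosphorylation"),   # matches S
            PTMRecord("R1", 4, "S", "phosphorylation"),   # sequence has T -> drop
            PTMRecord("R1", 3, "S", "phosphorylation"),   # duplicate -> collapse
            PTMRecord("R9", 1, "M", "acetylation"),       # unknown receptor -> drop
            PTMRecord("R1", 99, "S", "phosphorylation"),  # outside sequence -> drop
        ]
        kept = validate_ptm_sites(records, seqs)
        assert [(r.receptor, r.residue_index) for r in kept] == [("R1", 3)]


class TestPutativeRule:
    @pytest.mark.parametrize(
        "sift,polyphen,expected",
        [
            (0.03, 0.05, True),    # SIFT deleterious band
            (0.5, 0.05, False),    # tolerated + benign
            (0.5, 0.15, True),     # possibly damaging
            (0.05, None, True),    # boundary: SIFT <= 0.05 deleterious
            (None, 0.1, False),    # boundary: PolyPhen 0.1 still benign
            (None, None, False),
        ],
    )
    def test_rule(self, sift, polyphen, expected):
        assert is_putative_functional(sift, polyphen) is expected

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            is_putative_functional(1.5, None)


class TestAnnotateVariants:
    def test_position_in_two_registries_gets_both_categories(self, toy_segment_map):
        r3x50 = toy_segment_map.residue_of(GenericPosition("3", 50))
        anns = [
            FunctionalSiteAnnotation(
                "R1", "microswitch", generic_position=GenericPosition("3", 50)
            ),
            FunctionalSiteAnnotation(
                "R1", "g_protein_interface", generic_position=GenericPosition("3", 50)
            ),
        ]
        mv = MissenseVariant("R1", r3x50, "A", "V", 1, 100, sift=0.5, polyphen=0.0)
        df = annotate_variant_sites([mv], anns, {"R1": toy_segment_map})
        row = df.iloc[0]
        assert set(row["categories"].split(";")) == {"g_protein_interface", "microswitch"}
        assert row["known_functional"] and not row["putative_functional"]

    def test_ptm_site_matches_by_residue_index(self, toy_segment_map):
        anns = [FunctionalSiteAnnotation("R1", "ptm", residue_index=2)]
        mv = MissenseVariant("R1", 2, "A", "V", 1, 100)
        df = annotate_variant_sites([mv], anns, {"R1": toy_segment_map})
        assert df.iloc[0]["categories"] == "ptm"

    def test_unannotated_variant_has_no_flags(self, toy_segment_map):
        mv = MissenseVariant("R1", 1, "A", "V", 1, 100, sift=0.8, polyphen=0.02)
        df = annotate_variant_sites([mv], [], {"R1": toy_segment_map})
        row = df.iloc[0]
        assert row["categories"] == ""
        assert not row["known_functional"] and not row["putative_functional"]

    def test_variant_beyond_length_rejected(self, toy_segment_map):
        mv = MissenseVariant("R1", toy_segment_map.length + 1, "A", "V", 1, 100)
        with pytest.raises(ValueError):
            annotate_variant_sites([mv], [], {"R1": toy_segment_map})


def test_annotation_tsv_round_trip(tmp_path):
    anns = [
        FunctionalSiteAnnotation(
            "R1", "ligand_binding",
            generic_position=GenericPosition("5", 47), provenance="direct_structure",
        ),
        FunctionalSiteAnnotation(
            "R1", "ptm", residue_index=345, provenance="experimental_ptm"
        ),
    ]
    path = tmp_path / "sites.tsv"
    write_annotations_tsv(anns, path)
    back = read_annotations_tsv(path)
    assert len(back) == 2
    by_cat = {a.category: a for a in back}
    assert by_cat["ligand_binding"].generic_position == GenericPosition("5", 47)
    assert by_cat["ptm"].residue_index == 345


def test_planted_fraction_recovered_on_synthetic_variants(small_study):
    """With rho=1, the fraction of variants in planted sites matches the
    planted site fraction within binomial error."""
    n_in = sum(
        v.residue_index in small_study.functional_truth[v.receptor]
        for v in small_study.variants
    )
    n = len(small_study.variants)
    frac = small_study.config.functional_site_fraction
    se = (frac * (1 - frac) / n) ** 0.5
    assert abs(n_in / n - frac) < 4 * se + 0.01
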