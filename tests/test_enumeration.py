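"""Connectivity graphs, chain classification and candidate enumeration."""

import itertools

import networkx as nx
import pytest

from ligsieve import fixtures
from ligsieve.mmcif_model import parse_mmcif
from ligsieve.query_mapping import BirdEntry, ReferenceTables
from ligsieve.enumeration import (
    apply_enumeration_filters,
    build_connectivity_graph,
    chain_uniprot_map,
    classify_chain_as_peptide_ligand,
    classify_oligosaccharide,
    detect_protein_covalent_links,
    enumerate_candidates,
    ligand_space_graph,
    classify_polymer_chains,
    residues_of,
)

from conftest import simple_protein_ligand_builder, union_find_components


def _refs(**kw):
    base = dict(bird=[], counts={}, exclusion=set(), keep=set())
    base.update(kw)
    return ReferenceTables(**base)


def _scenario_structure(factory, sid, pdb):
    bundle = factory(sid)
    return parse_mmcif(bundle.cif_dir / f"{pdb}.cif")


class TestConnectivityGraph:
    def test_sequential_atom_residues_form_path(self, parse_builder):
        b = fixtures.CifBuilder("path", [1.8])
        b.add_entity("1", "polymer", "nat", "chain")
        b.add_poly_seq("1", "AAAAA")
        b.add_ref("A", "UNP", "P0TEST1", 1, 5)
        b.add_protein_chain("A", "1", 5)
        g = build_connectivity_graph(parse_builder(b))
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 4
        degrees = sorted(d for _, d in g.degree())
        assert degrees == [1, 1, 2, 2, 2]

    def test_intercalated_cycle_is_single_component(self, scenario_factory):
        st = _scenario_structure(scenario_factory, "S4", "ts04")
        g = build_connectivity_graph(st)
        chain_b = [r for r in g.nodes if r.chain == "B"]
        assert len(chain_b) == 11
        comp = nx.node_connected_component(g, chain_b[0])
        assert {r for r in comp if r.chain == "B"} == set(chain_b)
        assert len(comp) == 11

    def test_adjacent_hetatm_residues_not_implicitly_bonded(self,
                                                            parse_builder):
        b = simple_protein_ligand_builder()
        b.add_entity("3", "non-polymer", "syn", "x")
        b.add_residue("HETATM", "XA1", "X", 1,
                      fixtures.blob_atoms(fixtures.helix_ca(1)[0], 4), "3")
        b.add_residue("HETATM", "XA2", "X", 2,
                      fixtures.blob_atoms(fixtures.helix_ca(1)[0] + 3, 4), "3")
        g = build_connectivity_graph(parse_builder(b))
        xa = [r for r in g.nodes if r.chain == "X"]
        assert not g.has_edge(xa[0], xa[1])

    def test_dangling_covale_record_skipped(self, parse_builder):
        b = simple_protein_ligand_builder()
        b.add_conn("covale", ("Z", 99, "ZZZ", "C1"), ("B", 1, "LIG", "C1"))
        g = build_connectivity_graph(parse_builder(b))   # no exception
        assert all(r.chain != "Z" for r in g.nodes)

    def test_components_match_union_find_oracle(self, scenario_factory):
        for sid, pdb in (("S3", "ts03"), ("S4", "ts04"), ("S7", "ts07")):
            st = _scenario_structure(scenario_factory, sid, pdb)
            g = build_connectivity_graph(st)
            expected = union_find_components(list(g.nodes), list(g.edges))
            got = sorted((frozenset(c) for c in nx.connected_components(g)),
                         key=sorted)
            assert got == expected


class TestProteinCovalentLinks:
    def test_warhead_lysine_bond_reported_with_atoms(self, scenario_factory):
        st = _scenario_structure(scenario_factory, "S6", "ts06")
        g = build_connectivity_graph(st)
        links = detect_protein_covalent_links(st, g)
        assert len(links) == 1
        lig, prot, atoms = links[0]
        assert lig.comp_id == "CVX" and prot.comp_id == "LYS"
        assert atoms == ("C1", "NZ")

    def test_glycosylation_bond_detected(self, scenario_factory):
        st = _scenario_structure(scenario_factory, "S7", "ts07")
        g = build_connectivity_graph(st)
        links = detect_protein_covalent_links(st, g)
        assert any(l.comp_id == "NAG" and p.comp_id == "ASN"
                   for l, p, _ in links)

    def test_disulfide_records_ignored(self, parse_builder):
        b = simple_protein_ligand_builder()
        b.add_conn("disulf", ("A", 3, "ALA", "SG"), ("A", 9, "ALA", "SG"))
        st = parse_builder(b)
        g = build_connectivity_graph(st)
        assert detect_protein_covalent_links(st, g) == []


class TestChainClassification:
    def test_unmapped_synthetic_chain_is_ligand(self, scenario_factory):
        st = _scenario_structure(scenario_factory, "S5", "ts05")
        is_lig, reason = classify_chain_as_peptide_ligand("E", st)
        assert is_lig and reason == "unmapped-chain"

    def test_full_length_natural_protein_is_not_ligand(self,
                                                       scenario_factory):
        st = _scenario_structure(scenario_factory, "S11", "ts11")
        is_lig, reason = classify_chain_as_peptide_ligand(
            "L", st, uniprot_lengths={"P0TEST9": 36})
        assert not is_lig and reason == "full-length-protein"

    def test_bird_sequence_match_confirms_ligand(self, parse_builder):
        b = simple_protein_ligand_builder()
        b.add_entity("3", "polymer", "syn", "bird peptide")
        b.add_poly_seq("3", "AAAAAAA")
        b.add_ref("E", "UNP", "P0TEST5", 1, 7)
        b.add_protein_chain("E", "3", 7, origin=(9.0, 0.0, 0.0))
        st = parse_builder(b)
        bird = [BirdEntry("PRD_000042", "AAAAAAA", frozenset())]
        is_lig, reason = classify_chain_as_peptide_ligand("E", st, bird)
        assert is_lig and reason == "bird-match:PRD_000042"

    def test_short_synthetic_mapped_construct_is_ligand(self, parse_builder):
        b = simple_protein_ligand_builder()
        b.add_entity("3", "polymer", "syn", "mapped short construct")
        b.add_poly_seq("3", "A" * 13)
        b.add_ref("E", "UNP", "P0TEST7", 1, 13)
        b.add_protein_chain("E", "3", 13, origin=(9.0, 0.0, 0.0))
        st = parse_builder(b)
        is_lig, reason = classify_chain_as_peptide_ligand(
            "E", st, uniprot_lengths={"P0TEST7": 400})
        assert is_lig and reason == "synthetic-short-construct"

    def test_missing_chain_raises(self, parse_builder):
        st = parse_builder(simple_protein_ligand_builder())
        with pytest.raises(KeyError):
            classify_chain_as_peptide_ligand("Z", st)


class TestOligosaccharides:
    def test_n_glycosylation_tree_rejected(self, scenario_factory):
        st = _scenario_structure(scenario_factory, "S7", "ts07")
        g = build_connectivity_graph(st)
        is_lig, reason = classify_oligosaccharide(st.branches[0], g, st)
        assert not is_lig and reason == "N-glycosylation"

    def test_free_oligosaccharide_kept(self, scenario_factory):
        st = _scenario_structure(scenario_factory, "S8", "ts08")
        g = build_connectivity_graph(st)
        is_lig, reason = classify_oligosaccharide(st.branches[0], g, st)
        assert is_lig and reason == "free-oligosaccharide"

    def test_bird_matched_covalent_branch_kept_with_flag(self,
                                                         scenario_factory):
        st = _scenario_structure(scenario_factory, "S7", "ts07")
        g = build_connectivity_graph(st)
        bird = [BirdEntry("PRD_000900", "", frozenset({"ts07"}))]
        is_lig, reason = classify_oligosaccharide(st.branches[0], g, st, bird)
        assert is_lig and reason == "bird-match-covalent:PRD_000900"
        refs = _refs(bird=bird)
        cands = enumerate_candidates(st, g, refs)
        assert len(cands) == 1
        assert cands[0].kind == "bird_matched"
        assert "covalent" in cands[0].flags


class TestEnumeration:
    def test_fragment_pair_reassembled_into_one_candidate(self,
                                                          scenario_factory):
        st = _scenario_structure(scenario_factory, "S3", "ts03")
        g = build_connectivity_graph(st)
        cands = enumerate_candidates(st, g, _refs())
        assert len(cands) == 1
        assert sorted(cands[0].comp_codes) == ["DGL", "PHQ"]
        assert "reassembled_multi_residue" in cands[0].flags

    def test_peptide_chain_and_atp_both_enumerated(self, scenario_factory):
        st = _scenario_structure(scenario_factory, "S5", "ts05")
        g = build_connectivity_graph(st)
        cands = enumerate_candidates(st, g, _refs())
        kinds = sorted(c.kind for c in cands)
        assert kinds == ["chain_peptide", "small_molecule"]

    def test_glycosylation_only_structure_is_apo(self, scenario_factory):
        st = _scenario_structure(scenario_factory, "S7", "ts07")
        g = build_connectivity_graph(st)
        assert enumerate_candidates(st, g, _refs()) == []

    def test_no_residue_in_two_candidates(self, scenario_factory):
        for sid, pdb in (("S3", "ts03"), ("S5", "ts05"), ("S8", "ts08"),
                         ("S10", "ts10")):
            st = _scenario_structure(scenario_factory, sid, pdb)
            g = build_connectivity_graph(st)
            cands = enumerate_candidates(st, g, _refs())
            all_res = list(itertools.chain.from_iterable(
                c.residues for c in cands))
            assert len(all_res) == len(set(all_res))

    def test_candidates_match_component_oracle(self, scenario_factory):
        st = _scenario_structure(scenario_factory, "S3", "ts03")
        g = build_connectivity_graph(st)
        refs = _refs()
        _, protein_chains = classify_polymer_chains(st, refs)
        lig_g = ligand_space_graph(st, g, protein_chains)
        oracle = union_find_components(list(lig_g.nodes), list(lig_g.edges))
        oracle = [c for c in oracle
                  if any(r.record_kind == "HETATM" for r in c)]
        cands = enumerate_candidates(st, g, refs)
        got = sorted((frozenset(c.residues) for c in cands), key=sorted)
        assert got == sorted(oracle, key=sorted)

    def test_adding_covale_edge_never_increases_count(self, parse_builder):
        b = simple_protein_ligand_builder()
        b.add_entity("3", "non-polymer", "syn", "second ligand")
        b.add_residue("HETATM", "LG2", "C", 1,
                      fixtures.blob_atoms(fixtures.helix_ca(20)[5] * 1.5, 5),
                      "3")
        st_free = parse_builder(b)
        g = build_connectivity_graph(st_free)
        n_free = len(enumerate_candidates(st_free, g, _refs()))
        b.add_conn("covale", ("B", 1, "LIG", "C1"), ("C", 1, "LG2", "C1"))
        b.pdb_id = "tst2"
        st_bonded = parse_builder(b)
        g2 = build_connectivity_graph(st_bonded)
        n_bonded = len(enumerate_candidates(st_bonded, g2, _refs()))
        assert n_bonded == n_free - 1


class TestEnumerationFilters:
    def _small(self, parse_builder, code, n_atoms=6, copies=1):
        b = simple_protein_ligand_builder(lig_code=code, lig_atoms=n_atoms)
        for i in range(1, copies):
            b.add_residue("HETATM", code, "B", 1 + i,
                          fixtures.blob_atoms(
                              fixtures.helix_ca(20)[10] + 4 * (i + 1),
                              n_atoms), "2")
        st = parse_builder(b)
        g = build_connectivity_graph(st)
        return enumerate_candidates(st, g, _refs())

    def test_frequent_code_flagged_not_removed(self, parse_builder):
        cands = self._small(parse_builder, "GOL")
        out = apply_enumeration_filters(cands, {"GOL": 10000}, keep=set())
        assert len(out) == 1
        assert "frequent_ligand" in out[0].flags

    def test_keep_list_suppresses_frequent_flag(self, parse_builder):
        cands = self._small(parse_builder, "ATP")
        out = apply_enumeration_filters(cands, {"ATP": 5000}, keep={"ATP"})
        assert len(out) == 1
        assert "frequent_ligand" not in out[0].flags

    def test_more_than_ten_copies_removed(self, parse_builder):
        cands = self._small(parse_builder, "XYZ", copies=12)
        out = apply_enumeration_filters(cands, {}, keep=set())
        assert out == []

    def test_tiny_candidates_removed(self, parse_builder):
        cands = self._small(parse_builder, "O2X", n_atoms=2)
        out = apply_enumeration_filters(cands, {}, keep=set())
        assert out == []

    def test_no_survivor_below_heavy_atom_floor(self, parse_builder):
        for n in (2, 3, 5):
            cands = self._small(parse_builder, "LIG", n_atoms=n)
            out = apply_enumeration_filters(cands, {}, keep=set())
            assert all(c.heavy_atom_count >= 3 for c in out)
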