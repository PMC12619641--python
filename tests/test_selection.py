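"""Fragment subsumption, deduplication, superposition and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from ligsieve import fixtures
from ligsieve.mmcif_model import parse_mmcif
from ligsieve.query_mapping import ReferenceTables
from ligsieve.enumeration import (
    build_connectivity_graph,
    classify_polymer_chains,
    enumerate_candidates,
    ligand_space_graph,
)
from ligsieve.processing_filters import PocketRecord, pocket_gate
from ligsieve.selection import (
    AlignmentError,
    cluster_centroids,
    deduplicate_filter_mode,
    kabsch_superpose,
    ligand_centroid,
    remove_subsumed_fragments,
    superpose_to_reference,
    write_summary,
    SUMMARY_COLUMNS,
)

from conftest import quaternion_rmsd


def _refs():
    return ReferenceTables(bird=[], counts={}, exclusion=set(), keep=set())


def _fake_pocket(uid, comp, chain, seq, count, kind="small_molecule"):
    from ligsieve.enumeration import LigandCandidate, ResidueKey
    res = ResidueKey(chain=chain, auth_seq=seq, ins_code=None,
                     comp_id=comp, record_kind="HETATM")
    cand = LigandCandidate(ligand_uid=uid, kind=kind, residues=(res,),
                           heavy_atom_count=10)
    return PocketRecord(ligand_uid=uid, ligand_file=f"{uid}.pdb",
                        candidate=cand,
                        nearby_residues=[("A", i, "ALA")
                                         for i in range(count)],
                        pdb_id="tstp")


class TestSubsumedFragments:
    def test_fragment_connected_to_larger_unit_removed(self,
                                                       scenario_factory):
        # rebuild an S3-like situation where the fragment is its own
        # candidate: restrict a candidate to the PHQ residue only
        bundle = scenario_factory("S3")
        struct = parse_mmcif(bundle.cif_dir / "ts03.cif")
        graph = build_connectivity_graph(struct)
        refs = _refs()
        _, protein_chains = classify_polymer_chains(struct, refs)
        lig_graph = ligand_space_graph(struct, graph, protein_chains)
        full = enumerate_candidates(struct, graph, refs)[0]
        from dataclasses import replace
        phq_only = replace(full, ligand_uid="PHQ.B.1",
                           residues=tuple(r for r in full.residues
                                          if r.comp_id == "PHQ"))
        pocket = PocketRecord(ligand_uid="PHQ.B.1", ligand_file="x.pdb",
                              candidate=phq_only, nearby_residues=[],
                              pdb_id=struct.pdb_id)
        log = []
        kept = remove_subsumed_fragments([pocket],
                                         {struct.pdb_id: lig_graph}, log)
        assert kept == []
        assert any("SUBSUMED" in ln for ln in log)

    def test_disjoint_ligands_both_kept(self, scenario_factory):
        bundle = scenario_factory("S9")
        struct = parse_mmcif(bundle.cif_dir / "ts09.cif")
        graph = build_connectivity_graph(struct)
        refs = _refs()
        _, protein_chains = classify_polymer_chains(struct, refs)
        lig_graph = ligand_space_graph(struct, graph, protein_chains)
        cands = enumerate_candidates(struct, graph, refs)
        pockets = pocket_gate(cands, struct, {"A"})
        kept = remove_subsumed_fragments(pockets,
                                         {struct.pdb_id: lig_graph})
        assert len(kept) == len(pockets) == 2


class TestDeduplication:
    def test_copy_with_most_nearby_residues_selected(self):
        pockets = [_fake_pocket("5U6.A.1", "5U6", "A", 1, 18),
                   _fake_pocket("5U6.B.1", "5U6", "B", 1, 22),
                   _fake_pocket("5U6.C.1", "5U6", "C", 1, 20)]
        out = deduplicate_filter_mode(pockets)
        assert [p.ligand_uid for p in out] == ["5U6.B.1"]

    def test_tie_broken_lexicographically(self):
        pockets = [_fake_pocket("chain-F", "PEP", "F", 1, 15,
                                kind="chain_peptide"),
                   _fake_pocket("chain-E", "PEP", "E", 1, 15,
                                kind="chain_peptide")]
        out = deduplicate_filter_mode(pockets)
        assert [p.ligand_uid for p in out] == ["chain-E"]

    def test_single_ligand_unchanged(self):
        pockets = [_fake_pocket("LIG.A.1", "LIG", "A", 1, 9)]
        out = deduplicate_filter_mode(pockets)
        assert out == pockets

    def test_never_mutates_surviving_records(self):
        pockets = [_fake_pocket("5U6.A.1", "5U6", "A", 1, 18),
                   _fake_pocket("5U6.B.1", "5U6", "B", 1, 22)]
        before = tuple(pockets[1].candidate.residues)
        out = deduplicate_filter_mode(pockets)
        assert out[0].candidate.residues == before
        assert out[0].nearby_residues == pockets[1].nearby_residues


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)]])


class TestKabsch:
    def test_rigid_motion_recovered_exactly(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(25, 3)) * 5
        rot = _rotation([0, 0, 1], np.deg2rad(30.0))
        mobile = ref @ rot.T + np.array([3.0, -2.0, 1.0])
        sup = kabsch_superpose(mobile, ref)
        assert sup.rmsd < 1e-6
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_jitter_rmsd_matches_closed_form(self):
        # per-axis N(0, sigma^2) noise => E[rmsd] ~= sigma * sqrt(3)
        rng = np.random.default_rng(11)
        sigma = 0.1
        ref = rng.normal(size=(200, 3)) * 8
        mobile = ref + rng.normal(scale=sigma, size=ref.shape)
        sup = kabsch_superpose(mobile, ref)
        expected = sigma * np.sqrt(3.0)
        assert abs(sup.rmsd - expected) / expected < 0.2

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.normal(size=(10, 3)) * 4
            b = rng.normal(size=(10, 3)) * 4
            assert abs(kabsch_superpose(a, b).rmsd
                       - quaternion_rmsd(a, b)) < 1e-8

    def test_too_few_atoms_rejected(self):
        with pytest.raises(AlignmentError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSuperposeStructures:
    def test_rmsd_gate_excludes_with_warning(self, scenario_factory,
                                             tmp_path):
        bundle = scenario_factory("S12")
        ref = parse_mmcif(bundle.cif_dir / "tc01.cif")
        mob = parse_mmcif(bundle.cif_dir / "tc02.cif")
        log = []
        sup = superpose_to_reference(mob, ref, {"A"}, {"A"},
                                     rmsd_gate=3.5, log=log)
        assert sup is not None and sup.rmsd < 0.01   # rigid perturbation
        # force a failure with an absurd gate
        log2 = []
        sup2 = superpose_to_reference(mob, ref, {"A"}, {"A"},
                                      rmsd_gate=1e-9, log=log2)
        assert sup2 is None
        assert any("RMSD_EXCLUDED" in ln for ln in log2)

    def test_insufficient_pairs_is_distinct_error(self, scenario_factory):
        bundle = scenario_factory("S12")
        ref = parse_mmcif(bundle.cif_dir / "tc01.cif")
        mob = parse_mmcif(bundle.cif_dir / "tc02.cif")
        with pytest.raises(AlignmentError):
            superpose_to_reference(mob, ref, {"Z"}, {"Z"})


class TestCentroids:
    def test_mean_of_collinear_atoms(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [4, 0, 0]], float)
        assert np.allclose(pts.mean(axis=0), [2, 0, 0])

    def test_centroid_from_structure(self, scenario_factory):
        bundle = scenario_factory("S1")
        struct = parse_mmcif(bundle.cif_dir / "ts01.cif")
        cands = enumerate_candidates(struct,
                                     build_connectivity_graph(struct),
                                     _refs())
        pockets = pocket_gate(cands, struct, {"A"})
        cen = ligand_centroid(pockets[0], struct)
        from ligsieve.enumeration import heavy_atoms_of
        atoms = heavy_atoms_of(struct, pockets[0].candidate.residues)
        manual = np.mean([a.xyz for a in atoms], axis=0)
        assert np.allclose(cen, manual)

    def test_translation_equivariance(self, scenario_factory):
        from ligsieve.selection import Superposition
        bundle = scenario_factory("S1")
        struct = parse_mmcif(bundle.cif_dir / "ts01.cif")
        cands = enumerate_candidates(struct,
                                     build_connectivity_graph(struct),
                                     _refs())
        pockets = pocket_gate(cands, struct, {"A"})
        t = np.array([1.0, -2.0, 3.0])
        sup = Superposition(rotation=np.eye(3), translation=t, rmsd=0.0,
                            n_matched=3)
        assert np.allclose(ligand_centroid(pockets[0], struct, sup),
                           ligand_centroid(pockets[0], struct) + t)


class TestClustering:
    def test_two_close_centroids_merge(self):
        cls = cluster_centroids([np.zeros(3), np.array([5.0, 0, 0])])
        assert len(cls) == 1

    def test_two_distant_centroids_stay_apart(self):
        cls = cluster_centroids([np.zeros(3), np.array([12.0, 0, 0])])
        assert len(cls) == 2

    def test_sixteen_ligands_two_sites_two_clusters(self):
        rng = np.random.default_rng(5)
        site1 = np.zeros(3)
        site2 = np.array([30.0, 0.0, 0.0])
        pts = [site1 + rng.normal(scale=1.0, size=3) for _ in range(8)] + \
              [site2 + rng.normal(scale=1.0, size=3) for _ in range(8)]
        cls = cluster_centroids(pts)
        assert len(cls) == 2
        assert sorted(len(c.members) for c in cls) == [8, 8]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_threshold_properties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        # tight cloud: all pairwise < 10 => one cluster
        tight = rng.normal(scale=1.0, size=(n, 3))
        span = max(np.linalg.norm(a - b) for a in tight for b in tight)
        if span < 10.0:
            assert len(cluster_centroids(list(tight))) == 1
        # exploded set: min gap > 10 => all singletons
        sparse = np.array([[25.0 * i, 0.0, 0.0] for i in range(n)])
        assert len(cluster_centroids(list(sparse))) == n

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(9)
        pts = list(rng.normal(scale=15.0, size=(10, 3)))
        members = [("p", str(i)) for i in range(10)]
        base = cluster_centroids(pts, members)
        perm = list(rng.permutation(10))
        shuffled = cluster_centroids([pts[i] for i in perm],
                                     [members[i] for i in perm])
        def partition(cls):
            return sorted((frozenset(c.members) for c in cls), key=sorted)
        assert partition(base) == partition(shuffled)


class TestSummary:
    def test_row_count_and_schema(self, tmp_path):
        rows = [{c: "x" for c in SUMMARY_COLUMNS} for _ in range(2)]
        out = tmp_path / "summary.tsv"
        write_summary(rows, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == SUMMARY_COLUMNS
        assert len(lines) == 3
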