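"""Synthetic mmCIF scenario generation for offline, end-to-end testing.

Each scenario builds a small but syntactically complete PDBx/mmCIF entry
(idealised poly-alanine helices for protein chains; compact atom blobs for
small molecules), the matching reference tables (SIFTS, aliases, BIRD,
ligand counts, keep and exclusion lists, UniProt sequence lengths), a
query file, and a manifest of the ligand labels the pipeline is expected
to report.  The manifest is the regression oracle: running the full
pipeline on a scenario must reproduce it exactly.

Scenarios
---------
========  ==================================================================
S1        one typical HETATM small molecule next to the query protein
S2        apo structure (protein only)
S3        fragment (PHQ-style) covalently bonded to a second HETATM
          residue: must come back as a single reassembled 2-residue ligand
S4        cyclic 11-residue peptide chain with ATOM/HETATM-intercalated
          residues, connectivity only recoverable from ``covale`` records
S5        unmapped synthetic peptide chain plus an ATP molecule
S6        small molecule covalently bound to a lysine of the query chain
S7        N-glycosylation tree on an asparagine, no other ligands: the
          entry must be reported ligand-free
S8        free (unattached) oligosaccharide chain: a legitimate ligand
S9        frequent additive (GOL) next to a true ligand: GOL removed
S10       one ligand species in three copies on three chains: *filter*
          mode must keep exactly the copy with most pocket residues
S11       small natural full-length protein chain (36 residues, matching
          its UniProt length) that must NOT be classified as a peptide
S12       five structures of one query with ligand copies at two binding
          sites 30 Å apart: *cluster* mode must find exactly two clusters
========  ==================================================================

Accessions use the reserved test pattern ``P0TESTn``; the alias table maps
``Q0OLD1`` to ``P0TEST1`` and scenario S1 deposits its chain reference
under the secondary accession to exercise remediation end to end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

QUERY_ACCESSION = "P0TEST1"
SECONDARY_ACCESSION = "Q0OLD1"

KEEP_CODES = ["ATP", "ADP", "AMP", "GTP", "GDP", "GNP", "NAD", "NAP", "NDP",
              "FAD", "FMN", "HEM", "SAM", "SAH", "COA"]
EXCLUSION_CODES = ["HOH", "GOL", "EDO", "PEG", "SO4", "PO4", "CL", "NA",
                   "BEN", "DMS", "ACT", "TRS", "MES", "EPE", "FMT"]
LIGAND_COUNTS = {"LIG": 5, "ATP": 5000, "GOL": 10000, "5U6": 12, "T42": 3,
                 "CVX": 2, "PHQ": 12, "DGL": 4, "NAG": 9000, "BMA": 8000,
                 "FUC": 4000, "IDS": 40, "SGN": 38, "74D": 6}

ALL_SCENARIOS = ["S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9",
                 "S10", "S11", "S12"]

ONE_LETTER = {"ALA": "A", "LYS": "K", "ASN": "N", "GLY": "G", "SER": "S",
              "LEU": "L", "VAL": "V", "THR": "T", "GLU": "E", "ASP": "D"}


@dataclass
class ScenarioSpec:
    scenario_id: str
    seed: int = 0


@dataclass
class ScenarioBundle:
    scenario_id: str
    cif_dir: Path
    table_dir: Path
    queries_file: Path
    manifest_file: Path
    mode: str                       # selection mode the scenario targets
    expected: dict[str, list[str]]  # pdb_id → expected labels (multiset)
    expected_clusters: Optional[int] = None


# ---------------------------------------------------------------------------
# geometry

def helix_ca(n: int, origin=(0.0, 0.0, 0.0), rise=1.5, radius=2.3,
             turn_deg=100.0) -> np.ndarray:
    """Idealised alpha-helix C-alpha trace along +z."""
    t = np.deg2rad(turn_deg) * np.arange(n)
    xyz = np.stack([radius * np.cos(t), radius * np.sin(t),
                    rise * np.arange(n)], axis=1)
    return xyz + np.asarray(origin, dtype=float)


_BACKBONE_OFFSETS = [
    ("N", "N", (-1.20, 0.40, -0.50)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("C", "C", (1.20, 0.30, 0.50)),
    ("O", "O", (1.80, 1.30, 0.60)),
    ("CB", "C", (0.10, -1.40, 0.20)),
]

_LYS_EXTRA = [("CG", "C", (0.3, -2.7, 0.3)), ("CD", "C", (0.5, -4.0, 0.4)),
              ("CE", "C", (0.7, -5.3, 0.5)), ("NZ", "N", (0.9, -6.6, 0.6))]
_ASN_EXTRA = [("CG", "C", (0.3, -2.7, 0.3)), ("OD1", "O", (1.3, -3.4, 0.4)),
              ("ND2", "N", (-0.7, -3.5, 0.5))]


def residue_atoms(ca: np.ndarray, comp: str) -> list[tuple[str, str, np.ndarray]]:
    offs = list(_BACKBONE_OFFSETS)
    if comp == "LYS":
        offs += _LYS_EXTRA
    elif comp == "ASN":
        offs += _ASN_EXTRA
    return [(name, el, ca + np.asarray(off)) for name, el, off in offs]


def blob_atoms(center: np.ndarray, n: int, spread=1.0,
               element="C") -> list[tuple[str, str, np.ndarray]]:
    """A deterministic compact cluster of *n* heavy atoms around *center*."""
    out = []
    for i in range(n):
        ang = 2.0 * np.pi * i / max(n, 1)
        off = np.array([spread * np.cos(ang), spread * np.sin(ang),
                        0.4 * ((-1) ** i)])
        out.append((f"{element}{i + 1}", element, np.asarray(center) + off))
    return out


# ---------------------------------------------------------------------------
# mmCIF builder

class CifBuilder:
    def __init__(self, pdb_id: str, resolutions: Sequence[float] = (1.8,)):
        self.pdb_id = pdb_id.lower()
        self.resolutions = list(resolutions)
        self.entities: list[tuple[str, str, str, str]] = []
        self.poly_seqs: list[tuple[str, str]] = []
        self.refs: list[tuple[str, str, str, Optional[str], int, int]] = []
        self.atoms: list[tuple] = []
        self.conns: list[tuple] = []
        self.branch_entities: list[str] = []
        self.branch_scheme: list[tuple[str, str, str, int]] = []
        self._serial = 0

    def add_entity(self, eid: str, etype: str, src: str = "unknown",
                   desc: str = "?") -> None:
        self.entities.append((eid, etype, src, desc))

    def add_poly_seq(self, eid: str, seq: str) -> None:
        self.poly_seqs.append((eid, seq))

    def add_ref(self, chain: str, db_name: str, accession: Optional[str],
                beg: int = 1, end: int = 1) -> None:
        ref_id = str(len(self.refs) + 1)
        self.refs.append((ref_id, chain, db_name, accession, beg, end))

    def add_atom(self, record: str, name: str, element: str, comp: str,
                 chain: str, seq: int, xyz, entity: str,
                 occ: float = 1.0, alt: Optional[str] = None) -> None:
        self._serial += 1
        self.atoms.append((record, self._serial, name, element, comp, chain,
                           seq, xyz, entity, occ, alt))

    def add_residue(self, record: str, comp: str, chain: str, seq: int,
                    atoms: Iterable[tuple[str, str, np.ndarray]],
                    entity: str) -> None:
        for name, el, xyz in atoms:
            self.add_atom(record, name, el, comp, chain, seq, xyz, entity)

    def add_conn(self, conn_type: str, side1: tuple, side2: tuple,
                 dist: float = 1.5) -> None:
        # side = (chain, seq, comp, atom_name)
        self.conns.append((conn_type, side1, side2, dist))

    def add_branch(self, eid: str, chain: str,
                   monomers: Sequence[tuple[str, int]]) -> None:
        self.branch_entities.append(eid)
        for comp, num in monomers:
            self.branch_scheme.append((eid, chain, comp, num))

    # -- protein helpers ----------------------------------------------------

    def add_protein_chain(self, chain: str, eid: str, n_res: int,
                          origin=(0.0, 0.0, 0.0),
                          comps: Optional[dict[int, str]] = None,
                          record: str = "ATOM", start_seq: int = 1) -> None:
        comps = comps or {}
        cas = helix_ca(n_res, origin=origin)
        for i in range(n_res):
            comp = comps.get(start_seq + i, "ALA")
            self.add_residue(record, comp, chain, start_seq + i,
                             residue_atoms(cas[i], comp), eid)

    def text(self) -> str:
        L: list[str] = [f"data_{self.pdb_id.upper()}"]
        L.append(f"_entry.id {self.pdb_id.upper()}")
        if len(self.resolutions) == 1:
            L.append(f"_refine.ls_d_res_high {self.resolutions[0]:.2f}")
        elif self.resolutions:
            L += ["loop_", "_refine.ls_d_res_high"]
            L += [f"{r:.2f}" for r in self.resolutions]
        if self.entities:
            L += ["loop_", "_entity.id", "_entity.type",
                  "_entity.src_method", "_entity.pdbx_description"]
            for eid, etype, src, desc in self.entities:
                L.append(f"{eid} {etype} {src} '{desc}'")
        if self.poly_seqs:
            L += ["loop_", "_entity_poly.entity_id",
                  "_entity_poly.pdbx_seq_one_letter_code_can"]
            for eid, seq in self.poly_seqs:
                L.append(f"{eid} {seq}")
        if self.refs:
            L += ["loop_", "_struct_ref.id", "_struct_ref.db_name",
                  "_struct_ref.pdbx_db_accession"]
            for ref_id, _, db, acc, _, _ in self.refs:
                L.append(f"{ref_id} {db} {acc or '?'}")
            L += ["loop_", "_struct_ref_seq.ref_id",
                  "_struct_ref_seq.pdbx_strand_id",
                  "_struct_ref_seq.pdbx_db_accession",
                  "_struct_ref_seq.seq_align_beg",
                  "_struct_ref_seq.seq_align_end"]
            for ref_id, chain, _, acc, beg, end in self.refs:
                L.append(f"{ref_id} {chain} {acc or '?'} {beg} {end}")
        if self.conns:
            L += ["loop_", "_struct_conn.id", "_struct_conn.conn_type_id",
                  "_struct_conn.ptnr1_auth_asym_id",
                  "_struct_conn.ptnr1_auth_seq_id",
                  "_struct_conn.ptnr1_label_comp_id",
                  "_struct_conn.ptnr1_label_atom_id",
                  "_struct_conn.ptnr2_auth_asym_id",
                  "_struct_conn.ptnr2_auth_seq_id",
                  "_struct_conn.ptnr2_label_comp_id",
                  "_struct_conn.ptnr2_label_atom_id",
                  "_struct_conn.pdbx_dist_value"]
            for i, (ctype, s1, s2, dist) in enumerate(self.conns, 1):
                L.append(f"{ctype}{i} {ctype} {s1[0]} {s1[1]} {s1[2]} {s1[3]}"
                         f" {s2[0]} {s2[1]} {s2[2]} {s2[3]} {dist:.2f}")
        if self.branch_entities:
            L += ["loop_", "_pdbx_entity_branch.entity_id",
                  "_pdbx_entity_branch.type"]
            for eid in self.branch_entities:
                L.append(f"{eid} oligosaccharide")
            L += ["loop_", "_pdbx_branch_scheme.entity_id",
                  "_pdbx_branch_scheme.asym_id", "_pdbx_branch_scheme.mon_id",
                  "_pdbx_branch_scheme.num"]
            for eid, chain, comp, num in self.branch_scheme:
                L.append(f"{eid} {chain} {comp} {num}")
        L += ["loop_", "_atom_site.group_PDB", "_atom_site.id",
              "_atom_site.label_atom_id", "_atom_site.type_symbol",
              "_atom_site.label_comp_id", "_atom_site.auth_comp_id",
              "_atom_site.label_asym_id", "_atom_site.auth_asym_id",
              "_atom_site.label_seq_id", "_atom_site.auth_seq_id",
              "_atom_site.pdbx_PDB_ins_code", "_atom_site.label_alt_id",
              "_atom_site.occupancy", "_atom_site.Cartn_x",
              "_atom_site.Cartn_y", "_atom_site.Cartn_z",
              "_atom_site.label_entity_id", "_atom_site.pdbx_PDB_model_num"]
        for (rec, serial, name, el, comp, chain, seq, xyz, ent, occ,
             alt) in self.atoms:
            L.append(f"{rec} {serial} {name} {el} {comp} {comp} {chain} "
                     f"{chain} {seq} {seq} ? {alt or '.'} {occ:.2f} "
                     f"{xyz[0]:.3f} {xyz[1]:.3f} {xyz[2]:.3f} {ent} 1")
        return "\n".join(L) + "\n"

    def write(self, path: Path) -> None:
        path.write_text(self.text())


# ---------------------------------------------------------------------------
# reference tables

def write_tables(table_dir: Path,
                 sifts_rows: Iterable[tuple[str, str, str]],
                 bird_rows: Iterable[tuple[str, str, str]] = (),
                 lengths: Optional[dict[str, int]] = None) -> None:
    table_dir.mkdir(parents=True, exist_ok=True)
    with open(table_dir / "sifts.tsv", "w") as fh:
        fh.write("pdb_id\tchain\tuniprot\n")
        for pdb, chain, acc in sifts_rows:
            fh.write(f"{pdb}\t{chain}\t{acc}\n")
    with open(table_dir / "aliases.tsv", "w") as fh:
        fh.write(f"{SECONDARY_ACCESSION}\t{QUERY_ACCESSION}\n")
    with open(table_dir / "bird.tsv", "w") as fh:
        fh.write("prd_id\tsequence\tpdb_ids\n")
        for prd, seq, pdbs in bird_rows:
            fh.write(f"{prd}\t{seq}\t{pdbs}\n")
    with open(table_dir / "counts.tsv", "w") as fh:
        fh.write("code\tn_pdbs\n")
        for code, n in sorted(LIGAND_COUNTS.items()):
            fh.write(f"{code}\t{n}\n")
    with open(table_dir / "keep.txt", "w") as fh:
        fh.write("# common but legitimate ligands\n")
        fh.write("\n".join(KEEP_CODES) + "\n")
    with open(table_dir / "exclusion.txt", "w") as fh:
        fh.write("# solvents, additives, salts\n")
        fh.write("\n".join(EXCLUSION_CODES) + "\n")
    all_lengths = {QUERY_ACCESSION: 300, "P0TEST9": 36}
    all_lengths.update(lengths or {})
    with open(table_dir / "uniprot_lengths.tsv", "w") as fh:
        fh.write("accession\tlength\n")
        for acc, n in sorted(all_lengths.items()):
            fh.write(f"{acc}\t{n}\n")


def _write_manifest(path: Path, rows: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("pdb_id\texpected_label\n")
        for pdb, label in rows:
            fh.write(f"{pdb}\t{label}\n")


# ---------------------------------------------------------------------------
# scenario builders

def _surface_point(ca: np.ndarray, distance: float) -> np.ndarray:
    """A point *distance* Å radially outward from a helix C-alpha."""
    out = ca.copy()
    radial = ca[:2]
    norm = np.linalg.norm(radial)
    if norm < 1e-9:
        radial, norm = np.array([1.0, 0.0]), 1.0
    out[:2] = radial + radial / norm * distance
    return out


def _standard_protein(b: CifBuilder, accession: str = QUERY_ACCESSION,
                      n_res: int = 20,
                      comps: Optional[dict[int, str]] = None) -> np.ndarray:
    b.add_entity("1", "polymer", "nat", "query protein")
    seq = "".join(ONE_LETTER.get((comps or {}).get(i + 1, "ALA"), "A")
                  for i in range(n_res))
    b.add_poly_seq("1", seq)
    b.add_ref("A", "UNP", accession, 1, n_res)
    b.add_protein_chain("A", "1", n_res, comps=comps)
    return helix_ca(n_res)


def _build_s1() -> tuple[CifBuilder, list, list[tuple[str, str]]]:
    b = CifBuilder("ts01", [1.8])
    cas = _standard_protein(b, accession=SECONDARY_ACCESSION)
    b.add_entity("2", "non-polymer", "syn", "test ligand")
    center = _surface_point(cas[10], 4.0)
    b.add_residue("HETATM", "LIG", "B", 1, blob_atoms(center, 8), "2")
    sifts = [("ts01", "A", SECONDARY_ACCESSION)]
    return b, sifts, [("ts01", "LIG")]


def _build_s2() -> tuple[CifBuilder, list, list]:
    b = CifBuilder("ts02", [2.0, 2.3])
    _standard_protein(b)
    return b, [("ts02", "A", QUERY_ACCESSION)], []


def _build_s3() -> tuple[CifBuilder, list, list]:
    b = CifBuilder("ts03", [1.9])
    cas = _standard_protein(b)
    b.add_entity("2", "non-polymer", "syn", "carbobenzoxy fragment")
    b.add_entity("3", "non-polymer", "syn", "D-glutamate fragment")
    c1 = _surface_point(cas[8], 4.0)
    c2 = c1 + np.array([2.4, 0.6, 0.4])
    b.add_residue("HETATM", "PHQ", "B", 1, blob_atoms(c1, 7), "2")
    b.add_residue("HETATM", "DGL", "B", 2, blob_atoms(c2, 9), "3")
    b.add_conn("covale", ("B", 1, "PHQ", "C1"), ("B", 2, "DGL", "N1"))
    return b, [("ts03", "A", QUERY_ACCESSION)], [("ts03", "DGL-PHQ")]


def _build_s4() -> tuple[CifBuilder, list, list]:
    b = CifBuilder("ts04", [2.1])
    _standard_protein(b)
    # cyclic 11-residue peptide, residues alternating ATOM/HETATM, on a
    # ring next to the helix; connectivity carried only by covale records
    b.add_entity("2", "polymer", "syn", "cyclic peptide ligand")
    b.add_poly_seq("2", "X" * 11)
    b.add_ref("B", "PDB", "TS04", 1, 11)
    n = 11
    ring_center = np.array([8.0, 0.0, 8.0])
    comps = {}
    for i in range(n):
        seq = i + 1
        ang = 2 * np.pi * i / n
        center = ring_center + np.array([0.0, 3.8 * np.cos(ang),
                                         3.8 * np.sin(ang)])
        record = "ATOM" if i % 2 == 0 else "HETATM"
        comp = "ALA" if record == "ATOM" else "MLE"
        comps[seq] = comp
        atoms = [("N", "N", center + np.array([-0.8, 0.3, 0.0])),
                 ("CA", "C", center),
                 ("C", "C", center + np.array([0.8, -0.3, 0.2]))]
        b.add_residue(record, comp, "B", seq, atoms, "2")
    for i in range(1, n):   # 10 covale records joining residues 1..11
        b.add_conn("covale", ("B", i, comps[i], "C"),
                   ("B", i + 1, comps[i + 1], "N"))
    return b, [("ts04", "A", QUERY_ACCESSION)], [("ts04", "chain-B")]


def _build_s5() -> tuple[CifBuilder, list, list]:
    b = CifBuilder("ts05", [2.2])
    cas = _standard_protein(b)
    b.add_entity("2", "non-polymer", "syn", "adenosine triphosphate")
    b.add_residue("HETATM", "ATP", "C", 1,
                  blob_atoms(_surface_point(cas[4], 4.0), 31), "2")
    b.add_entity("3", "polymer", "syn", "7-residue peptide ligand")
    b.add_poly_seq("3", "AAAAAAA")
    b.add_ref("E", "PDB", "TS05", 1, 7)
    b.add_protein_chain("E", "3", 7, origin=(7.5, 0.0, 6.0))
    return b, [("ts05", "A", QUERY_ACCESSION)], \
        [("ts05", "ATP"), ("ts05", "chain-E")]


def _build_s6() -> tuple[CifBuilder, list, list]:
    b = CifBuilder("ts06", [1.7])
    comps = {10: "LYS"}
    _standard_protein(b, comps=comps)
    nz = helix_ca(20)[9] + np.array([0.9, -6.6, 0.6])
    b.add_entity("2", "non-polymer", "syn", "covalent warhead")
    b.add_residue("HETATM", "CVX", "B", 1,
                  blob_atoms(nz + np.array([0.0, -2.2, 0.0]), 6), "2")
    b.add_conn("covale", ("B", 1, "CVX", "C1"), ("A", 10, "LYS", "NZ"))
    return b, [("ts06", "A", QUERY_ACCESSION)], [("ts06", "CVX")]


def _glyco_tree(b: CifBuilder, chain: str, eid: str, root: np.ndarray,
                monomers: Sequence[str], attach_to: Optional[tuple] = None,
                ) -> None:
    """A linear sugar tree; internal covale links plus optional root link."""
    b.add_entity(eid, "branched", "man", "oligosaccharide")
    scheme = []
    prev = None
    for i, comp in enumerate(monomers):
        seq = i + 1
        center = root + np.array([0.0, -2.6 * (i + 1), 0.3 * i])
        b.add_residue("HETATM", comp, chain, seq,
                      blob_atoms(center, 11, element="C"), eid)
        scheme.append((comp, seq))
        if prev is not None:
            b.add_conn("covale", (chain, prev[1], prev[0], "O4"),
                       (chain, seq, comp, "C1"))
        prev = (comp, seq)
    b.add_branch(eid, chain, scheme)
    if attach_to is not None:
        b.add_conn("covale", (chain, 1, monomers[0], "C1"), attach_to)


def _build_s7() -> tuple[CifBuilder, list, list]:
    b = CifBuilder("ts07", [1.9])
    comps = {10: "ASN"}
    _standard_protein(b, comps=comps)
    nd2 = helix_ca(20)[9] + np.array([-0.7, -3.5, 0.5])
    _glyco_tree(b, "C", "2", nd2 + np.array([0.0, -1.5, 0.0]),
                ["NAG", "NAG", "BMA"], attach_to=("A", 10, "ASN", "ND2"))
    return b, [("ts07", "A", QUERY_ACCESSION)], []


def _build_s8() -> tuple[CifBuilder, list, list]:
    b = CifBuilder("ts08", [2.0])
    cas = _standard_protein(b)
    root = _surface_point(cas[10], 4.0)
    _glyco_tree(b, "C", "2", root, ["IDS", "SGN", "IDS", "SGN", "IDS", "SGN"])
    return b, [("ts08", "A", QUERY_ACCESSION)], [("ts08", "chain-C")]


def _build_s9() -> tuple[CifBuilder, list, list]:
    b = CifBuilder("ts09", [1.6])
    cas = _standard_protein(b)
    b.add_entity("2", "non-polymer", "syn", "glycerol")
    b.add_residue("HETATM", "GOL", "B", 1,
                  blob_atoms(_surface_point(cas[4], 4.0), 6), "2")
    b.add_entity("3", "non-polymer", "syn", "true ligand")
    b.add_residue("HETATM", "LIG", "C", 1,
                  blob_atoms(_surface_point(cas[14], 4.0), 9), "3")
    return b, [("ts09", "A", QUERY_ACCESSION)], [("ts09", "LIG")]


def _build_s10() -> tuple[CifBuilder, list, list]:
    b = CifBuilder("ts10", [2.4])
    b.add_entity("1", "polymer", "nat", "query protein, three chains")
    b.add_poly_seq("1", "A" * 20)
    for chain, x0 in (("A", 0.0), ("B", 12.0), ("C", 24.0)):
        b.add_ref(chain, "UNP", QUERY_ACCESSION, 1, 20)
        b.add_protein_chain(chain, "1", 20, origin=(x0, 0.0, 0.0))
    b.add_entity("2", "non-polymer", "syn", "triplicated ligand")
    # copy D: outside chain A; copy E: between chains A and B (most
    # neighbours); copy F: outside chain C
    b.add_residue("HETATM", "5U6", "D", 1,
                  blob_atoms(np.array([-5.0, 0.0, 15.0]), 10), "2")
    b.add_residue("HETATM", "5U6", "E", 1,
                  blob_atoms(np.array([6.0, 0.0, 15.0]), 10), "2")
    b.add_residue("HETATM", "5U6", "F", 1,
                  blob_atoms(np.array([29.0, 0.0, 15.0]), 10), "2")
    sifts = [("ts10", c, QUERY_ACCESSION) for c in "ABC"]
    return b, sifts, [("ts10", "5U6")]


def _build_s11() -> tuple[CifBuilder, list, list]:
    b = CifBuilder("ts11", [1.8])
    cas = _standard_protein(b)
    # a genuinely small natural protein whose theoretical sequence covers
    # its entire UniProt entry: must stay a protein, never a peptide ligand
    b.add_entity("2", "polymer", "nat", "small natural protein")
    b.add_poly_seq("2", "A" * 36)
    b.add_ref("L", "UNP", "P0TEST9", 1, 36)
    b.add_protein_chain("L", "2", 36, origin=(10.0, 0.0, 0.0))
    b.add_entity("3", "non-polymer", "syn", "small-molecule ligand")
    b.add_residue("HETATM", "T42", "B", 1,
                  blob_atoms(_surface_point(cas[10], 4.0), 12), "3")
    sifts = [("ts11", "A", QUERY_ACCESSION), ("ts11", "L", "P0TEST9")]
    return b, sifts, [("ts11", "T42")]


_BUILDERS = {"S1": _build_s1, "S2": _build_s2, "S3": _build_s3,
             "S4": _build_s4, "S5": _build_s5, "S6": _build_s6,
             "S7": _build_s7, "S8": _build_s8, "S9": _build_s9,
             "S10": _build_s10, "S11": _build_s11}


def generate_scenario(scenario_id: str, out_dir: str | os.PathLike,
                      seed: int = 0) -> ScenarioBundle:
    """Write one scenario's mmCIF file(s), tables, queries and manifest."""
    scenario_id = scenario_id.upper()
    if scenario_id not in ALL_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id!r}; choose from "
                         + ", ".join(ALL_SCENARIOS))
    out = Path(out_dir)
    if scenario_id == "S12":
        return generate_cluster_set(out_dir=out, seed=seed)
    cif_dir = out / "cifs"
    cif_dir.mkdir(parents=True, exist_ok=True)
    b, sifts, manifest = _BUILDERS[scenario_id]()
    b.write(cif_dir / f"{b.pdb_id}.cif")
    write_tables(out / "tables", sifts)
    queries = out / "queries.txt"
    queries.write_text(QUERY_ACCESSION + "\n")
    manifest_file = out / "manifest.tsv"
    _write_manifest(manifest_file, manifest)
    expected: dict[str, list[str]] = {b.pdb_id: []}
    for pdb, label in manifest:
        expected.setdefault(pdb, []).append(label)
    return ScenarioBundle(scenario_id=scenario_id, cif_dir=cif_dir,
                          table_dir=out / "tables", queries_file=queries,
                          manifest_file=manifest_file, mode="filter",
                          expected=expected)


def generate_cluster_set(out_dir: str | os.PathLike,
                         n_structures: int = 5,
                         site_separation: float = 30.0,
                         jitter: float = 1.0,
                         n_ligands: int = 16,
                         seed: int = 0) -> ScenarioBundle:
    """Five structures of one query with ligands at two distant sites.

    Each structure is the same 45-residue helix rigidly rotated and
    translated; ligand copies sit at one of two binding sites separated by
    *site_separation* Å, with N(0, jitter²) positional noise.  The
    manifest declares the ground-truth number of clusters (2 for the
    default geometry).
    """
    if site_separation <= 0 or jitter < 0:
        raise ValueError("need site_separation > 0 and jitter >= 0")
    out = Path(out_dir)
    cif_dir = out / "cifs"
    cif_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_res = 45
    site1 = np.array([5.5, 0.0, 12.0])
    site2 = site1 + np.array([0.0, 0.0, site_separation])
    # distribute ligand copies over structures, both sites represented
    per_structure = [n_ligands // n_structures] * n_structures
    for i in range(n_ligands - sum(per_structure)):
        per_structure[i] += 1
    sifts = []
    manifest: list[tuple[str, str]] = []
    expected: dict[str, list[str]] = {}
    for s in range(n_structures):
        pdb_id = f"tc{s + 1:02d}"
        b = CifBuilder(pdb_id, [2.0])
        _standard_protein(b, n_res=n_res)
        chains = "LMNOPQ"
        for j in range(per_structure[s]):
            site = site1 if (s + j) % 2 == 0 else site2
            center = site + rng.normal(0.0, jitter, 3)
            b.add_entity(str(2 + j), "non-polymer", "syn", "cluster ligand")
            b.add_residue("HETATM", "LIG", chains[j], 1,
                          blob_atoms(center, 8), str(2 + j))
            manifest.append((pdb_id, "LIG"))
            expected.setdefault(pdb_id, []).append("LIG")
        # rigid perturbation of the whole entry (undone by superposition)
        ang = float(rng.uniform(0, 2 * np.pi))
        c, si = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -si, 0.0], [si, c, 0.0], [0.0, 0.0, 1.0]])
        shift = rng.uniform(-20.0, 20.0, 3)
        if s > 0:
            b.atoms = [(rec, serial, name, el, comp, chain, seq,
                        rot @ np.asarray(xyz) + shift, ent, occ, alt)
                       for (rec, serial, name, el, comp, chain, seq, xyz,
                            ent, occ, alt) in b.atoms]
        b.write(cif_dir / f"{pdb_id}.cif")
        sifts.append((pdb_id, "A", QUERY_ACCESSION))
    write_tables(out / "tables", sifts)
    queries = out / "queries.txt"
    queries.write_text(QUERY_ACCESSION + "\n")
    manifest_file = out / "manifest.tsv"
    _write_manifest(manifest_file, manifest)
    return ScenarioBundle(scenario_id="S12", cif_dir=cif_dir,
                          table_dir=out / "tables", queries_file=queries,
                          manifest_file=manifest_file, mode="cluster",
                          expected=expected, expected_clusters=2)
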