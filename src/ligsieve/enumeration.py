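"""Candidate-ligand enumeration from a parsed structure.

The enumeration walks four routes and partitions the structure's residues:

1. polymer chains re-classified as peptide ligands (unmapped chains,
   synthetic short constructs, exact BIRD sequence matches), extended with
   any HETATM residues covalently bonded to them;
2. branched (oligosaccharide) entities, kept unless they are glycosylation
   groups attached to a protein chain;
3. every remaining connected component of the covalent-connectivity graph
   that contains at least one HETATM residue and no protein residue --
   this is what reassembles multi-residue ligands whose fragments carry
   separate component codes (split ATOM/HETATM deposition);
4. non-polymer / macrolide entities (already covered by route 3 in
   practice, since their residues are HETATM components).

Connectivity: residues with sequential numbering in the ATOM group of one
chain are assumed bonded; HETATM residues are bonded only where an explicit
``covale`` record in ``_struct_conn`` says so.

Enumeration-stage filters: component codes occurring in more than 250 PDB
entries are *flagged* as probable additives (unless kept by the keep-list);
candidates with fewer than 3 heavy atoms, or species with more than 10
copies in one structure, are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from ligsieve.mmcif_model import AtomSite, BranchInfo, Structure
from ligsieve.query_mapping import AccessionAliasTable, BirdEntry, ReferenceTables

logger = logging.getLogger(__name__)

#: the 20 canonical amino acids plus selenomethionine; modified residues
#: inside UniProt-mapped chains are treated as protein, not ligand.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}

WATER_CODES = {"HOH", "DOD", "WAT"}

#: glycosylation acceptor residues (N- and O-linked)
GLYCO_ACCEPTORS = {"ASN", "SER", "THR"}

FREQUENT_LIGAND_THRESHOLD = 250
MIN_HEAVY_ATOMS = 3
MAX_COPIES = 10
PEPTIDE_ALPHA = 0.8   # resolved length >= alpha * theoretical length
PEPTIDE_BETA = 0.5    # theoretical length <= beta * UniProt full length


@dataclass(frozen=True, order=True)
class ResidueKey:
    chain: str
    auth_seq: int
    ins_code: Optional[str]
    comp_id: str
    record_kind: str

    def label(self) -> str:
        ins = self.ins_code or ""
        return f"{self.chain}:{self.auth_seq}{ins}:{self.comp_id}"


@dataclass
class LigandCandidate:
    ligand_uid: str
    kind: str                        # small_molecule | chain_peptide | oligosaccharide | bird_matched
    residues: tuple[ResidueKey, ...]
    heavy_atom_count: int
    covalent_to_protein: bool = False
    prd_id: Optional[str] = None
    flags: set[str] = field(default_factory=set)

    @property
    def comp_codes(self) -> tuple[str, ...]:
        return tuple(r.comp_id for r in self.residues)

    def normalized_label(self) -> str:
        """Label used for benchmarking: code for single-residue small
        molecules, ``chain-X`` for chain-encoded ligands, hyphen-joined
        sorted codes for reassembled multi-residue molecules."""
        if self.kind in ("chain_peptide", "oligosaccharide") or (
                self.kind == "bird_matched" and len(self.residues) > 1
                and len({r.chain for r in self.residues}) == 1
                and self.ligand_uid.startswith("chain-")):
            return f"chain-{self.residues[0].chain}"
        if len(self.residues) == 1:
            return self.residues[0].comp_id
        return "-".join(sorted({r.comp_id for r in self.residues}))


# ---------------------------------------------------------------------------
# residue bookkeeping

def residues_of(structure: Structure) -> list[ResidueKey]:
    """Distinct residues, in order of first appearance in the atom table."""
    seen: dict[tuple, ResidueKey] = {}
    for a in structure.atoms:
        k = (a.auth_chain, a.auth_seq, a.ins_code)
        if k not in seen:
            seen[k] = ResidueKey(chain=a.auth_chain, auth_seq=a.auth_seq,
                                 ins_code=a.ins_code, comp_id=a.comp_id,
                                 record_kind=a.record_kind)
    return list(seen.values())


def heavy_atoms_of(structure: Structure,
                   residues: Iterable[ResidueKey]) -> list[AtomSite]:
    keys = {(r.chain, r.auth_seq, r.ins_code) for r in residues}
    return [a for a in structure.atoms
            if (a.auth_chain, a.auth_seq, a.ins_code) in keys
            and not a.is_hydrogen]


def chain_uniprot_map(structure: Structure,
                      aliases: AccessionAliasTable | None = None,
                      ) -> dict[str, set[str]]:
    """auth chain → set of primary UniProt accessions from ``_struct_ref_seq``.

    Self-referenced chains (db PDB) and chains without any reference map to
    an empty set.
    """
    aliases = aliases or AccessionAliasTable()
    out: dict[str, set[str]] = {c: set() for c in structure.polymer_chains()}
    for ref in structure.chain_refs:
        if ref.db_name.upper() == "UNP" and ref.accession:
            out.setdefault(ref.chain, set()).add(
                aliases.remediate(ref.accession))
    return out


# ---------------------------------------------------------------------------
# connectivity graph

def build_connectivity_graph(structure: Structure) -> "nx.Graph":
    """Undirected covalent-connectivity graph over residues.

    Nodes are all residues.  Edges: every ``covale`` record from
    ``_struct_conn`` (verbatim), plus implicit backbone edges between
    residues with consecutive numbering in the ATOM group of one chain.
    HETATM residues never gain implicit edges.  A covale record pointing at
    a residue that does not exist is logged and skipped.
    """
    g = nx.Graph()
    res = residues_of(structure)
    index: dict[tuple[str, int], ResidueKey] = {}
    for r in res:
        g.add_node(r)
        if r.ins_code is None:
            index[(r.chain, r.auth_seq)] = r
    # implicit sequential edges between consecutive ATOM residues of a chain
    by_chain: dict[str, list[ResidueKey]] = {}
    for r in res:
        if r.record_kind == "ATOM":
            by_chain.setdefault(r.chain, []).append(r)
    for chain_res in by_chain.values():
        chain_res.sort(key=lambda r: (r.auth_seq, r.ins_code or ""))
        for a, b in zip(chain_res, chain_res[1:]):
            if b.auth_seq - a.auth_seq == 1:
                g.add_edge(a, b, kind="sequential")
    # explicit covalent edges
    for conn in structure.connections:
        if conn.conn_type != "covale":
            continue
        r1 = index.get((conn.side1.chain, conn.side1.auth_seq))
        r2 = index.get((conn.side2.chain, conn.side2.auth_seq))
        if r1 is None or r2 is None:
            logger.warning("covale record references missing residue: %s / %s",
                           conn.side1, conn.side2)
            continue
        if r1 != r2:
            g.add_edge(r1, r2, kind="covale",
                       atoms=(conn.side1.atom_name, conn.side2.atom_name),
                       atom_of={r1: conn.side1.atom_name,
                                r2: conn.side2.atom_name})
    return g


def detect_protein_covalent_links(structure: Structure, graph: "nx.Graph",
                                  protein_chains: set[str] | None = None,
                                  ) -> list[tuple[ResidueKey, ResidueKey,
                                                  tuple[str, str]]]:
    """Covalent bonds between a protein residue and a non-protein partner.

    Returns (non-protein residue, protein residue, (atom, atom)) triples --
    the precise atoms come straight from the ``covale`` records.  *protein
    chains* defaults to the UniProt-mapped polymer chains.
    """
    if protein_chains is None:
        cmap = chain_uniprot_map(structure)
        protein_chains = {c for c, accs in cmap.items() if accs}
    links = []
    for a, b, data in graph.edges(data=True):
        if data.get("kind") != "covale":
            continue
        atom_of = data.get("atom_of", {})
        a_protein = a.chain in protein_chains and a.comp_id in STANDARD_AA
        b_protein = b.chain in protein_chains and b.comp_id in STANDARD_AA
        if a_protein and not b_protein:
            links.append((b, a, (atom_of.get(b, "?"), atom_of.get(a, "?"))))
        elif b_protein and not a_protein:
            links.append((a, b, (atom_of.get(a, "?"), atom_of.get(b, "?"))))
    return links


# ---------------------------------------------------------------------------
# chain classification

def classify_chain_as_peptide_ligand(chain: str,
                                     structure: Structure,
                                     bird: Iterable[BirdEntry] = (),
                                     chain_accessions: Mapping[str, set] | None = None,
                                     uniprot_lengths: Mapping[str, int] | None = None,
                                     alpha: float = PEPTIDE_ALPHA,
                                     beta: float = PEPTIDE_BETA,
                                     ) -> tuple[bool, str]:
    """Decide whether a polymer *chain* is a peptide ligand.

    A chain is a ligand when

    a. it has no UniProt mapping (self-referenced deposition), or
    b. it is UniProt-mapped but the entity is a synthetic polymer whose
       resolved sequence covers at least ``alpha`` of the theoretical
       sequence, and whose theoretical sequence is at most ``beta`` of the
       full-length UniProt sequence (a deliberately short construct), or
    c. its one-letter sequence exactly matches a BIRD reference sequence.

    Returns (decision, reason) where the reason records the branch that
    fired: ``bird-match``, ``unmapped-chain``, ``synthetic-short-construct``,
    ``full-length-protein`` or ``mapped-protein``.
    """
    entity_id = structure.entity_of_chain(chain)
    if entity_id is None:
        raise KeyError(f"chain {chain!r} not present in structure "
                       f"{structure.pdb_id}")
    entity = structure.entities.get(entity_id)
    theoretical = structure.theoretical_seqs.get(entity_id, "")

    if theoretical:
        for entry in bird:
            if entry.sequence and entry.sequence == theoretical.upper():
                return True, f"bird-match:{entry.prd_id}"

    if chain_accessions is None:
        chain_accessions = chain_uniprot_map(structure)
    accessions = chain_accessions.get(chain, set())
    if not accessions:
        return True, "unmapped-chain"

    full = max(((uniprot_lengths or {}).get(acc, 0) for acc in accessions),
               default=0)
    if entity is not None and entity.src_method == "syn" and theoretical:
        resolved = structure.resolved_sequence_length(chain)
        if (resolved >= alpha * len(theoretical) and full
                and len(theoretical) <= beta * full):
            return True, "synthetic-short-construct"
    if full and theoretical and len(theoretical) > beta * full:
        return False, "full-length-protein"
    return False, "mapped-protein"


def classify_oligosaccharide(branch: BranchInfo,
                             graph: "nx.Graph",
                             structure: Structure,
                             bird: Iterable[BirdEntry] = (),
                             protein_chains: set[str] | None = None,
                             ) -> tuple[bool, str]:
    """Decide whether a branched entity is a ligand or a glycosylation group.

    A branch covalently attached to a glycosylation acceptor residue
    (ASN/SER/THR) of a UniProt-mapped protein chain is a glycosylation
    group -- unless it is BIRD-matched, in which case it is kept as a
    candidate and flagged covalent.  Unattached branches are free
    oligosaccharide ligands.
    """
    if protein_chains is None:
        cmap = chain_uniprot_map(structure)
        protein_chains = {c for c, accs in cmap.items() if accs}
    branch_residues = {r for r in graph.nodes
                       if r.chain in branch.chains}
    attached = False
    acceptor = None
    for r in branch_residues:
        for nb in graph.neighbors(r):
            if nb.chain in protein_chains and nb.comp_id in STANDARD_AA:
                attached = True
                if nb.comp_id in GLYCO_ACCEPTORS:
                    acceptor = nb.comp_id
    if not attached:
        return True, "free-oligosaccharide"
    prd = _branch_bird_match(branch, structure, bird)
    if prd is not None:
        return True, f"bird-match-covalent:{prd}"
    kind = "N-glycosylation" if acceptor == "ASN" else "O-glycosylation" \
        if acceptor in ("SER", "THR") else "glycosylation"
    return False, kind


def _branch_bird_match(branch: BranchInfo, structure: Structure,
                       bird: Iterable[BirdEntry]) -> Optional[str]:
    # saccharide BIRD entries carry no one-letter sequence; match by the
    # PRD-to-PDB association or by the hyphen-joined monomer string
    monomer_str = "-".join(m for m, _ in branch.monomers)
    for entry in bird:
        if structure.pdb_id in entry.pdb_ids:
            return entry.prd_id
        if entry.sequence and monomer_str and entry.sequence == monomer_str:
            return entry.prd_id
    return None


# ---------------------------------------------------------------------------
# enumeration

def classify_polymer_chains(structure: Structure,
                            refs: ReferenceTables,
                            chain_accessions: Mapping[str, set] | None = None,
                            alpha: float = PEPTIDE_ALPHA,
                            beta: float = PEPTIDE_BETA,
                            log: list[str] | None = None,
                            ) -> tuple[dict[str, str], set[str]]:
    """Split polymer chains into peptide-ligand chains and protein chains."""
    if chain_accessions is None:
        chain_accessions = chain_uniprot_map(structure, refs.aliases)
    branch_chains: set[str] = set()
    for b in structure.branches:
        branch_chains |= set(b.chains)
    peptide_chains: dict[str, str] = {}
    protein_chains: set[str] = set()
    for chain in sorted(structure.polymer_chains()):
        if chain in branch_chains:
            continue
        is_lig, reason = classify_chain_as_peptide_ligand(
            chain, structure, refs.bird, chain_accessions,
            refs.uniprot_lengths, alpha, beta)
        if log is not None:
            log.append(f"{structure.pdb_id}\tPEPTIDE_DECISION\t{chain}\t"
                       f"{'ligand' if is_lig else 'protein'}\t{reason}")
        if is_lig:
            peptide_chains[chain] = reason
        else:
            protein_chains.add(chain)
    return peptide_chains, protein_chains


def ligand_space_graph(structure: Structure, graph: "nx.Graph",
                       protein_chains: set[str]) -> "nx.Graph":
    """Subgraph of *graph* without protein-chain residues and waters."""
    water_entities = {e.entity_id for e in structure.entities.values()
                      if e.entity_type == "water"}
    water_res = {(a.auth_chain, a.auth_seq, a.ins_code)
                 for a in structure.atoms
                 if a.entity_id in water_entities or a.comp_id in WATER_CODES}
    nodes = [r for r in graph.nodes
             if r.chain not in protein_chains
             and (r.chain, r.auth_seq, r.ins_code) not in water_res]
    return graph.subgraph(nodes)


def enumerate_candidates(structure: Structure,
                         graph: "nx.Graph",
                         refs: ReferenceTables | None = None,
                         chain_accessions: Mapping[str, set] | None = None,
                         log: list[str] | None = None,
                         alpha: float = PEPTIDE_ALPHA,
                         beta: float = PEPTIDE_BETA,
                         ) -> list[LigandCandidate]:
    """Enumerate every candidate ligand in *structure* (may be empty: apo).

    The returned candidates partition the structure's non-protein,
    non-water residues: no residue belongs to two candidates.
    """
    refs = refs or ReferenceTables(bird=[], counts={}, exclusion=set(),
                                   keep=set())
    if chain_accessions is None:
        chain_accessions = chain_uniprot_map(structure, refs.aliases)
    log = log if log is not None else []

    water_entities = {e.entity_id for e in structure.entities.values()
                      if e.entity_type == "water"}
    water_chains_res = {(a.auth_chain, a.auth_seq, a.ins_code)
                        for a in structure.atoms
                        if a.entity_id in water_entities
                        or a.comp_id in WATER_CODES}

    branch_chains: set[str] = set()
    for b in structure.branches:
        branch_chains |= set(b.chains)

    # 1. classify polymer chains
    peptide_chains, protein_chains = classify_polymer_chains(
        structure, refs, chain_accessions, alpha, beta, log)

    assigned: set[ResidueKey] = set()
    candidates: list[LigandCandidate] = []

    def is_water(r: ResidueKey) -> bool:
        return (r.chain, r.auth_seq, r.ins_code) in water_chains_res

    def is_protein_res(r: ResidueKey) -> bool:
        return r.chain in protein_chains

    # subgraph without protein residues and waters: ligand connectivity space
    lig_nodes = [r for r in graph.nodes
                 if not is_protein_res(r) and not is_water(r)]
    lig_graph = graph.subgraph(lig_nodes)

    def covalent_to_protein(residues: Iterable[ResidueKey]) -> bool:
        for r in residues:
            for nb in graph.neighbors(r):
                if is_protein_res(nb) and \
                        graph.edges[r, nb].get("kind") == "covale":
                    return True
        return False

    # 2. chain-peptide candidates, extended with covalently bonded HETATM
    for chain, reason in sorted(peptide_chains.items()):
        chain_res = sorted(r for r in lig_graph.nodes if r.chain == chain)
        if not chain_res:
            continue
        component: set[ResidueKey] = set()
        for r in chain_res:
            if r not in component:
                component |= nx.node_connected_component(lig_graph, r)
        component -= {r for r in component if r.chain in branch_chains}
        residues = tuple(sorted(component))
        prd = reason.split(":", 1)[1] if reason.startswith("bird-match") else None
        kind = "bird_matched" if prd else "chain_peptide"
        flags = set()
        if len({r.chain for r in residues}) > 1 or any(
                r.chain != chain for r in residues):
            flags.add("reassembled_multi_residue")
        cov = covalent_to_protein(residues)
        if cov:
            flags.add("covalent")
        candidates.append(LigandCandidate(
            ligand_uid=f"chain-{chain}", kind=kind, residues=residues,
            heavy_atom_count=len(heavy_atoms_of(structure, residues)),
            covalent_to_protein=cov, prd_id=prd, flags=flags))
        assigned |= component

    # 3. branched entities
    for branch in structure.branches:
        b_res = tuple(sorted(r for r in lig_graph.nodes
                             if r.chain in branch.chains and r not in assigned))
        if not b_res:
            continue
        is_lig, reason = classify_oligosaccharide(
            branch, graph, structure, refs.bird, protein_chains)
        assigned |= set(b_res)
        if not is_lig:
            log.append(f"{structure.pdb_id}\tGLYCOSYLATION_EXCLUDED\t"
                       f"{b_res[0].chain}\t{reason}")
            continue
        prd = reason.split(":", 1)[1] if "bird-match" in reason else None
        kind = "bird_matched" if prd else "oligosaccharide"
        cov = covalent_to_protein(b_res)
        flags = {"covalent"} if cov else set()
        if cov:
            log.append(f"{structure.pdb_id}\tCOVALENT_LINK\t"
                       f"chain-{b_res[0].chain}\tcovalent oligosaccharide "
                       f"kept as candidate ({reason})")
        candidates.append(LigandCandidate(
            ligand_uid=f"chain-{b_res[0].chain}", kind=kind, residues=b_res,
            heavy_atom_count=len(heavy_atoms_of(structure, b_res)),
            covalent_to_protein=cov, prd_id=prd, flags=flags))

    # 4. remaining connected components with >= 1 HETATM residue
    copy_counter: dict[str, int] = {}
    for component in sorted(nx.connected_components(lig_graph),
                            key=lambda c: min(c)):
        component = set(component) - assigned
        if not component:
            continue
        if not any(r.record_kind == "HETATM" for r in component):
            continue
        residues = tuple(sorted(component))
        assigned |= component
        codes = sorted({r.comp_id for r in residues})
        base = codes[0] if len(residues) == 1 else "-".join(codes)
        key = f"{base}.{residues[0].chain}"
        copy_counter[key] = copy_counter.get(key, 0) + 1
        uid = f"{key}.{copy_counter[key]}"
        flags = set()
        if len(residues) > 1:
            flags.add("reassembled_multi_residue")
            log.append(f"{structure.pdb_id}\tREASSEMBLED\t{uid}\t"
                       f"{len(residues)} residues: "
                       + ";".join(r.label() for r in residues))
        cov = covalent_to_protein(residues)
        if cov:
            flags.add("covalent")
            log.append(f"{structure.pdb_id}\tCOVALENT_LINK\t{uid}\t"
                       "covalently bound to protein")
        candidates.append(LigandCandidate(
            ligand_uid=uid, kind="small_molecule", residues=residues,
            heavy_atom_count=len(heavy_atoms_of(structure, residues)),
            covalent_to_protein=cov, flags=flags))

    return candidates


def apply_enumeration_filters(candidates: list[LigandCandidate],
                              counts: Mapping[str, int],
                              keep: set[str],
                              log: list[str] | None = None,
                              pdb_id: str = "",
                              frequent_threshold: int = FREQUENT_LIGAND_THRESHOLD,
                              min_heavy_atoms: int = MIN_HEAVY_ATOMS,
                              max_copies: int = MAX_COPIES,
                              ) -> list[LigandCandidate]:
    """Flag frequent ligands; drop tiny candidates and over-copied species.

    The frequent-ligand rule only *flags* (final removal is driven by the
    exclusion list downstream); the heavy-atom and copy-count rules remove.
    """
    log = log if log is not None else []
    kept: list[LigandCandidate] = []
    code_copies: dict[str, int] = {}
    for c in candidates:
        if c.kind == "small_molecule" and len(c.residues) == 1:
            code_copies[c.residues[0].comp_id] = \
                code_copies.get(c.residues[0].comp_id, 0) + 1
    for c in candidates:
        if c.heavy_atom_count < min_heavy_atoms:
            log.append(f"{pdb_id}\tEXCLUDED\t{c.ligand_uid}\t"
                       f"fewer than {min_heavy_atoms} heavy atoms")
            continue
        if c.kind == "small_molecule" and len(c.residues) == 1:
            code = c.residues[0].comp_id
            if code_copies[code] > max_copies:
                log.append(f"{pdb_id}\tEXCLUDED\t{c.ligand_uid}\t"
                           f"more than {max_copies} copies of {code}")
                continue
            if counts.get(code, 0) > frequent_threshold and code not in keep:
                c.flags.add("frequent_ligand")
                log.append(f"{pdb_id}\tFREQUENT_LIGAND\t{c.ligand_uid}\t"
                           f"{code} occurs in {counts[code]} PDB entries")
        kept.append(c)
    return kept
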