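"""Typed in-memory model of a PDBx/mmCIF entry and PDB-format subset writing.

Parsing is delegated to :mod:`gemmi`; the categories relevant to ligand
extraction (``_atom_site``, ``_entity``, ``_entity_poly``, ``_struct_ref`` /
``_struct_ref_seq``, ``_struct_conn``, ``_pdbx_entity_branch``,
``_pdbx_branch_scheme`` and the resolution items) are lifted into plain
dataclasses so that downstream logic never touches the CIF layer.

Conventions
-----------
* ``auth_*`` chain and residue identifiers are used for everything
  user-facing; ``label_*`` identifiers are kept only for entity bookkeeping.
* Only model 1 is retained when a file holds several models.
* Hydrogens are kept in the atom table but every distance or size
  computation downstream works on heavy atoms only.
* When several resolution values are reported the *highest* (worst) one is
  the effective resolution of the entry.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional

import gemmi


class MmcifParseError(ValueError):
    """Raised when a file cannot be read or lacks the mandatory categories."""


@dataclass(frozen=True)
class AtomSite:
    record_kind: str            # "ATOM" | "HETATM"
    atom_name: str
    element: str
    comp_id: str
    auth_chain: str
    label_chain: str
    auth_seq: int
    ins_code: Optional[str]
    alt_loc: Optional[str]
    occupancy: float
    xyz: tuple[float, float, float]
    entity_id: str
    model_num: int = 1

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass(frozen=True)
class EntityInfo:
    entity_id: str
    entity_type: str            # polymer | non-polymer | branched | water | macrolide
    src_method: str             # syn | nat | man | unknown
    description: str = ""
    chains: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ChainDbRef:
    chain: str
    db_name: str                # "UNP" | "PDB" | other
    accession: Optional[str]
    seq_begin: int = 0
    seq_end: int = 0

    @property
    def is_self_reference(self) -> bool:
        return self.db_name.upper() == "PDB"


@dataclass(frozen=True)
class ConnSide:
    chain: str
    auth_seq: int
    comp_id: str
    atom_name: str


@dataclass(frozen=True)
class StructConnRecord:
    conn_type: str              # covale | disulf | metalc | hydrog | ...
    side1: ConnSide
    side2: ConnSide
    distance: Optional[float] = None


@dataclass(frozen=True)
class BranchInfo:
    entity_id: str
    monomers: tuple[tuple[str, int], ...]   # (comp_id, branch position)
    chains: frozenset[str] = frozenset()


@dataclass
class Structure:
    pdb_id: str
    resolutions: list[float]
    atoms: list[AtomSite]
    entities: dict[str, EntityInfo]
    chain_refs: list[ChainDbRef]
    connections: list[StructConnRecord]
    branches: list[BranchInfo]
    theoretical_seqs: dict[str, str] = field(default_factory=dict)

    def polymer_chains(self) -> set[str]:
        out: set[str] = set()
        for ent in self.entities.values():
            if ent.entity_type == "polymer":
                out |= set(ent.chains)
        return out

    def chains_of_entity(self, entity_id: str) -> set[str]:
        return {a.auth_chain for a in self.atoms if a.entity_id == entity_id}

    def entity_of_chain(self, chain: str) -> Optional[str]:
        for a in self.atoms:
            if a.auth_chain == chain:
                return a.entity_id
        return None

    def refs_for_chain(self, chain: str) -> list[ChainDbRef]:
        return [r for r in self.chain_refs if r.chain == chain]

    def resolved_sequence_length(self, chain: str) -> int:
        """Number of distinct residues actually modelled in *chain*."""
        return len({(a.auth_seq, a.ins_code) for a in self.atoms
                    if a.auth_chain == chain})


def effective_resolution(structure: Structure) -> Optional[float]:
    """Worst (numerically highest) reported resolution, or None if absent."""
    if not structure.resolutions:
        return None
    return max(structure.resolutions)


# ---------------------------------------------------------------------------
# parsing

def _first(block: gemmi.cif.Block, tags: Iterable[str]) -> Optional[str]:
    for tag in tags:
        v = block.find_value(tag)
        if v is not None and v not in ("?", "."):
            return gemmi.cif.as_string(v)
    return None


def _opt(v: str) -> Optional[str]:
    return None if v in ("?", ".", "") else v


def _parse_resolutions(block: gemmi.cif.Block) -> list[float]:
    vals: list[float] = []
    for tag in ("_refine.ls_d_res_high",
                "_reflns.d_resolution_high",
                "_em_3d_reconstruction.resolution"):
        for raw in block.find_values(tag):
            raw = _opt(gemmi.cif.as_string(raw))
            if raw is None:
                continue
            try:
                vals.append(float(raw))
            except ValueError:
                continue
        if vals:
            break
    return vals


def _parse_atoms(block: gemmi.cif.Block) -> list[AtomSite]:
    cols = ["group_PDB", "label_atom_id", "type_symbol", "label_comp_id",
            "?auth_comp_id", "auth_asym_id", "?label_asym_id", "auth_seq_id",
            "?label_seq_id", "?pdbx_PDB_ins_code", "?label_alt_id",
            "?occupancy", "Cartn_x", "Cartn_y", "Cartn_z",
            "?label_entity_id", "?pdbx_PDB_model_num"]
    table = block.find("_atom_site.", cols)
    if not table:
        raise MmcifParseError("no usable _atom_site category")
    atoms: list[AtomSite] = []
    for row in table:
        def cell(i: int) -> str:
            if not row.has(i):
                return ""
            return gemmi.cif.as_string(row[i])

        model = int(cell(16)) if _opt(cell(16)) else 1
        comp = _opt(cell(4)) or cell(3)
        xyz = (float(cell(12)), float(cell(13)), float(cell(14)))
        if not all(math.isfinite(c) for c in xyz):
            raise MmcifParseError(f"non-finite coordinates in {block.name}")
        occ_raw = _opt(cell(11))
        atoms.append(AtomSite(
            record_kind=cell(0).upper(),
            atom_name=cell(1),
            element=cell(2).upper(),
            comp_id=comp.upper(),
            auth_chain=cell(5),
            label_chain=_opt(cell(6)) or cell(5),
            auth_seq=int(cell(7)),
            ins_code=_opt(cell(9)),
            alt_loc=_opt(cell(10)),
            occupancy=float(occ_raw) if occ_raw else 1.0,
            xyz=xyz,
            entity_id=_opt(cell(15)) or "?",
            model_num=model,
        ))
    models = {a.model_num for a in atoms}
    if len(models) > 1:
        keep = min(models)
        atoms = [a for a in atoms if a.model_num == keep]
    return atoms


def _parse_entities(block: gemmi.cif.Block,
                    atoms: list[AtomSite]) -> dict[str, EntityInfo]:
    chains_by_entity: dict[str, set[str]] = {}
    for a in atoms:
        chains_by_entity.setdefault(a.entity_id, set()).add(a.auth_chain)
    entities: dict[str, EntityInfo] = {}
    table = block.find("_entity.", ["id", "type", "?src_method",
                                    "?pdbx_description"])
    for row in table:
        eid = gemmi.cif.as_string(row[0])
        etype = gemmi.cif.as_string(row[1]).lower()
        src = "unknown"
        if row.has(2) and _opt(gemmi.cif.as_string(row[2])):
            src = gemmi.cif.as_string(row[2]).lower()
        desc = ""
        if row.has(3) and _opt(gemmi.cif.as_string(row[3])):
            desc = gemmi.cif.as_string(row[3])
        entities[eid] = EntityInfo(
            entity_id=eid, entity_type=etype, src_method=src,
            description=desc,
            chains=frozenset(chains_by_entity.get(eid, set())))
    # entities referenced by atoms but absent from _entity
    for eid, chains in chains_by_entity.items():
        if eid not in entities:
            entities[eid] = EntityInfo(entity_id=eid, entity_type="non-polymer",
                                       src_method="unknown",
                                       chains=frozenset(chains))
    return entities


def _parse_chain_refs(block: gemmi.cif.Block) -> list[ChainDbRef]:
    refs_meta: dict[str, tuple[str, Optional[str]]] = {}
    for row in block.find("_struct_ref.", ["id", "db_name",
                                           "?pdbx_db_accession"]):
        acc = None
        if row.has(2):
            acc = _opt(gemmi.cif.as_string(row[2]))
        refs_meta[gemmi.cif.as_string(row[0])] = (
            gemmi.cif.as_string(row[1]).upper(), acc)
    out: list[ChainDbRef] = []
    for row in block.find("_struct_ref_seq.", [
            "ref_id", "pdbx_strand_id", "?pdbx_db_accession",
            "?seq_align_beg", "?seq_align_end"]):
        ref_id = gemmi.cif.as_string(row[0])
        chain = gemmi.cif.as_string(row[1])
        db_name, acc = refs_meta.get(ref_id, ("UNK", None))
        if row.has(2) and _opt(gemmi.cif.as_string(row[2])):
            acc = gemmi.cif.as_string(row[2])
        beg = int(gemmi.cif.as_string(row[3])) if row.has(3) and _opt(
            gemmi.cif.as_string(row[3])) else 0
        end = int(gemmi.cif.as_string(row[4])) if row.has(4) and _opt(
            gemmi.cif.as_string(row[4])) else 0
        out.append(ChainDbRef(chain=chain, db_name=db_name, accession=acc,
                              seq_begin=beg, seq_end=end))
    return out


def _parse_connections(block: gemmi.cif.Block) -> list[StructConnRecord]:
    out: list[StructConnRecord] = []
    for row in block.find("_struct_conn.", [
            "conn_type_id",
            "ptnr1_auth_asym_id", "ptnr1_auth_seq_id", "ptnr1_label_comp_id",
            "ptnr1_label_atom_id",
            "ptnr2_auth_asym_id", "ptnr2_auth_seq_id", "ptnr2_label_comp_id",
            "ptnr2_label_atom_id", "?pdbx_dist_value"]):
        def s(i: int) -> str:
            return gemmi.cif.as_string(row[i])

        dist = None
        if row.has(9) and _opt(s(9)):
            try:
                dist = float(s(9))
            except ValueError:
                dist = None
        side1 = ConnSide(s(1), int(s(2)), s(3).upper(), s(4))
        side2 = ConnSide(s(5), int(s(6)), s(7).upper(), s(8))
        out.append(StructConnRecord(conn_type=s(0).lower(), side1=side1,
                                    side2=side2, distance=dist))
    return out


def _parse_branches(block: gemmi.cif.Block,
                    atoms: list[AtomSite]) -> list[BranchInfo]:
    branch_entities = []
    for row in block.find("_pdbx_entity_branch.", ["entity_id", "?type"]):
        branch_entities.append(gemmi.cif.as_string(row[0]))
    monomers: dict[str, list[tuple[str, int]]] = {}
    for row in block.find("_pdbx_branch_scheme.", ["entity_id", "mon_id",
                                                   "num"]):
        eid = gemmi.cif.as_string(row[0])
        monomers.setdefault(eid, []).append(
            (gemmi.cif.as_string(row[1]).upper(),
             int(gemmi.cif.as_string(row[2]))))
    out = []
    for eid in branch_entities:
        chains = frozenset(a.auth_chain for a in atoms if a.entity_id == eid)
        mons = tuple(sorted(monomers.get(eid, []), key=lambda m: m[1]))
        out.append(BranchInfo(entity_id=eid, monomers=mons, chains=chains))
    return out


def parse_mmcif(path: str | os.PathLike) -> Structure:
    """Parse a PDBx/mmCIF file into a :class:`Structure`.

    Missing optional categories give empty collections; a missing resolution
    gives an empty ``resolutions`` list (the caller decides whether that
    excludes the entry).  Alternate locations are *not* resolved here; call
    :func:`resolve_altlocs` before any downstream use.
    """
    path = os.fspath(path)
    try:
        doc = gemmi.cif.read(path)
    except Exception as exc:
        raise MmcifParseError(f"cannot read mmCIF file {path!r}: {exc}") from exc
    block = doc.sole_block()
    atoms = _parse_atoms(block)
    pdb_id = (_first(block, ["_entry.id"]) or block.name or "xxxx").lower()
    entities = _parse_entities(block, atoms)
    # promote entity types for branched entities found only via _pdbx_entity_branch
    branches = _parse_branches(block, atoms)
    for b in branches:
        ent = entities.get(b.entity_id)
        if ent is not None and ent.entity_type != "branched":
            entities[b.entity_id] = replace(ent, entity_type="branched")
    seqs: dict[str, str] = {}
    for row in block.find("_entity_poly.", [
            "entity_id", "?pdbx_seq_one_letter_code_can",
            "?pdbx_seq_one_letter_code"]):
        seq = None
        for i in (1, 2):
            if row.has(i) and _opt(gemmi.cif.as_string(row[i])):
                seq = gemmi.cif.as_string(row[i])
                break
        if seq:
            seqs[gemmi.cif.as_string(row[0])] = "".join(seq.split())
    return Structure(
        pdb_id=pdb_id,
        resolutions=_parse_resolutions(block),
        atoms=atoms,
        entities=entities,
        chain_refs=_parse_chain_refs(block),
        connections=_parse_connections(block),
        branches=branches,
        theoretical_seqs=seqs,
    )


# ---------------------------------------------------------------------------
# transforms

def resolve_altlocs(structure: Structure) -> Structure:
    """Keep one atom per (chain, residue, atom name) alternate-location group.

    The survivor is the alternate with maximal occupancy; ties go to the
    lexicographically smallest alt-loc identifier.  Idempotent.
    """
    best: dict[tuple, AtomSite] = {}
    order: list[tuple] = []
    for a in structure.atoms:
        key = (a.auth_chain, a.auth_seq, a.ins_code, a.atom_name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        else:
            if (a.occupancy, _alt_rank(a)) > (cur.occupancy, _alt_rank(cur)):
                best[key] = a
    kept = [replace(best[k], alt_loc=None) for k in order]
    return replace_atoms(structure, kept)


def _alt_rank(a: AtomSite) -> float:
    # higher rank wins; smaller alt_loc letter should win ties
    if a.alt_loc is None:
        return 0.0
    return -ord(a.alt_loc[0])


def replace_atoms(structure: Structure, atoms: list[AtomSite]) -> Structure:
    return Structure(
        pdb_id=structure.pdb_id,
        resolutions=list(structure.resolutions),
        atoms=atoms,
        entities=dict(structure.entities),
        chain_refs=list(structure.chain_refs),
        connections=list(structure.connections),
        branches=list(structure.branches),
        theoretical_seqs=dict(structure.theoretical_seqs),
    )


class UnmappedLigandCodeError(KeyError):
    """A 5-character chemical component code has no short-code mapping."""


def shorten_ligand_codes(structure: Structure,
                         code_map: Mapping[str, str]) -> Structure:
    """Replace 5-character component codes by their short aliases everywhere.

    The map must cover every 5-character code present in the structure;
    an uncovered code raises :class:`UnmappedLigandCodeError` naming it.
    """
    longs = {a.comp_id for a in structure.atoms if len(a.comp_id) == 5}
    missing = sorted(c for c in longs if c not in code_map)
    if missing:
        raise UnmappedLigandCodeError(
            "no short code for 5-character ligand code(s): "
            + ", ".join(missing))
    if not longs:
        return structure

    def conv(code: str) -> str:
        return code_map[code] if len(code) == 5 else code

    atoms = [replace(a, comp_id=conv(a.comp_id)) for a in structure.atoms]
    conns = [StructConnRecord(
        conn_type=c.conn_type,
        side1=replace(c.side1, comp_id=conv(c.side1.comp_id)),
        side2=replace(c.side2, comp_id=conv(c.side2.comp_id)),
        distance=c.distance) for c in structure.connections]
    branches = [BranchInfo(entity_id=b.entity_id,
                           monomers=tuple((conv(m), p) for m, p in b.monomers),
                           chains=b.chains)
                for b in structure.branches]
    out = replace_atoms(structure, atoms)
    out.connections = conns
    out.branches = branches
    return out


# ---------------------------------------------------------------------------
# PDB writing

def write_pdb_subset(structure: Structure,
                     selector: Callable[[AtomSite], bool],
                     path: str | os.PathLike) -> None:
    """Write the atoms matched by *selector* as a fixed-column PDB file.

    Coordinates are written exactly as stored (to PDB's 3-decimal
    precision); chain and residue identifiers use the auth_* numbering.
    An empty selection is an error.
    """
    selected = [a for a in structure.atoms if selector(a)]
    if not selected:
        raise ValueError("empty atom selection for PDB output")
    lines = []
    serial = 0
    prev_chain = None
    for a in selected:
        serial += 1
        if prev_chain is not None and a.auth_chain != prev_chain:
            lines.append("TER")
        prev_chain = a.auth_chain
        name = a.atom_name
        # PDB atom-name column convention: element right-aligned in cols 13-14
        if len(name) < 4 and len(a.element) == 1:
            name = f" {name}"
        lines.append(
            f"{a.record_kind:<6}{serial:>5} {name:<4}{'':1}"
            f"{a.comp_id:>3} {a.auth_chain[:1]}{a.auth_seq:>4}"
            f"{a.ins_code or '':1}   "
            f"{a.xyz[0]:>8.3f}{a.xyz[1]:>8.3f}{a.xyz[2]:>8.3f}"
            f"{a.occupancy:>6.2f}{0.0:>6.2f}          "
            f"{a.element:>2}")
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
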