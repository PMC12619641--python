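"""Exclusion-list removal, query-presence check and 6 Å pocket gating.

The pocket gate keeps only ligands with at least one heavy atom within the
cutoff (default 6 Å, boundary inclusive) of a heavy atom of a chain mapped
to the queried accession.  The stored pocket lists every nearby polymer
residue regardless of chain, at residue-level granularity: a residue is
"nearby" as soon as any of its heavy atoms is in range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from ligsieve.mmcif_model import Structure
from ligsieve.query_mapping import AccessionAliasTable
from ligsieve.enumeration import (
    LigandCandidate,
    ResidueKey,
    heavy_atoms_of,
    residues_of,
)

POCKET_CUTOFF = 6.0


@dataclass
class PocketRecord:
    ligand_uid: str
    ligand_file: str
    candidate: LigandCandidate
    nearby_residues: list[tuple[str, int, str]]   # (chain, auth_seq, comp_id)
    query_contact: bool = True
    pdb_id: str = ""

    @property
    def residue_count(self) -> int:
        return len(self.nearby_residues)

    @property
    def contact_chains(self) -> list[str]:
        return sorted({c for c, _, _ in self.nearby_residues})


def filter_exclusion_list(candidates: Iterable[LigandCandidate],
                          exclusion: set[str],
                          log: list[str] | None = None,
                          pdb_id: str = "",
                          ) -> list[LigandCandidate]:
    """Drop single-residue small molecules on the solvent/additive list.

    Multi-residue candidates are never removed here: a listed code that is
    merely a fragment of a larger reassembled ligand stays.
    """
    log = log if log is not None else []
    kept = []
    for c in candidates:
        if (c.kind == "small_molecule" and len(c.residues) == 1
                and c.residues[0].comp_id in exclusion):
            log.append(f"{pdb_id}\tEXCLUSION_LIST\t{c.ligand_uid}\t"
                       f"{c.residues[0].comp_id} is a solvent/additive/salt")
            continue
        kept.append(c)
    return kept


def require_query_chain(structure: Structure, query: str,
                        aliases: AccessionAliasTable | None = None) -> bool:
    """True iff some chain reference remediates to the query's accession."""
    aliases = aliases or AccessionAliasTable()
    primary = aliases.remediate(query)
    for ref in structure.chain_refs:
        if ref.accession and aliases.remediate(ref.accession) == primary:
            return True
    return False


def pocket_gate(candidates: Iterable[LigandCandidate],
                structure: Structure,
                query_chains: set[str],
                cutoff: float = POCKET_CUTOFF,
                log: list[str] | None = None,
                ) -> list[PocketRecord]:
    """Collect <=cutoff neighbours per ligand; keep query-contacting ligands.

    Nearby residues are polymer residues (any chain) with at least one
    heavy atom within *cutoff* of at least one ligand heavy atom, excluding
    the ligand's own residues.  A candidate with no nearby residue on a
    query chain is discarded with a log event.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    log = log if log is not None else []
    polymer_chains = structure.polymer_chains()
    poly_atoms = [a for a in structure.atoms
                  if a.auth_chain in polymer_chains and not a.is_hydrogen]
    records: list[PocketRecord] = []
    if poly_atoms:
        coords = np.array([a.xyz for a in poly_atoms])
        tree = cKDTree(coords)
    for cand in candidates:
        own = {(r.chain, r.auth_seq, r.ins_code) for r in cand.residues}
        lig_atoms = heavy_atoms_of(structure, cand.residues)
        if not lig_atoms or not poly_atoms:
            log.append(f"{structure.pdb_id}\tNO_QUERY_CONTACT\t"
                       f"{cand.ligand_uid}\tno atoms to measure")
            continue
        lig_xyz = np.array([a.xyz for a in lig_atoms])
        idx = sorted({j for js in tree.query_ball_point(lig_xyz, cutoff)
                      for j in js})
        nearby: list[tuple[str, int, str]] = []
        seen: set[tuple] = set()
        for j in idx:
            a = poly_atoms[j]
            key = (a.auth_chain, a.auth_seq, a.ins_code)
            if key in own or key in seen:
                continue
            seen.add(key)
            nearby.append((a.auth_chain, a.auth_seq, a.comp_id))
        nearby.sort()
        if not any(c in query_chains for c, _, _ in nearby):
            log.append(f"{structure.pdb_id}\tNO_QUERY_CONTACT\t"
                       f"{cand.ligand_uid}\tligand present but does not "
                       "contact query chains")
            continue
        records.append(PocketRecord(
            ligand_uid=cand.ligand_uid,
            ligand_file=f"{structure.pdb_id}_{cand.ligand_uid}.pdb",
            candidate=cand,
            nearby_residues=nearby,
            query_contact=True,
            pdb_id=structure.pdb_id,
        ))
    return records


def write_pocket_file(records: Iterable[PocketRecord], path) -> None:
    """Pocket info TSV: one row per surviving ligand."""
    with open(path, "w") as fh:
        fh.write("ligand_file\tpdb_id\tligand_uid\tresidue_count\tresidues\n")
        for rec in records:
            res = ";".join(f"{c}:{n}:{comp}"
                           for c, n, comp in rec.nearby_residues)
            fh.write(f"{rec.ligand_file}\t{rec.pdb_id}\t{rec.ligand_uid}\t"
                     f"{rec.residue_count}\t{res}\n")
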