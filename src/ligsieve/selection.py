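"""Ligand selection: *filter* (dedup) and *cluster* (superpose + group) modes.

*filter* keeps one representative per unique ligand structure -- the copy
with the most pocket residues.  *cluster* superposes each structure onto a
reference (first file in name-sorted order) with a Kabsch least-squares
fit on shared C-alpha atoms, rejects poor alignments (RMSD > 3.5 Å),
computes per-ligand heavy-atom centroids and groups them by complete-
linkage agglomerative clustering with a 10 Å distance threshold, so that
no two members of one cluster are ever more than 10 Å apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from ligsieve.mmcif_model import Structure
from ligsieve.enumeration import ResidueKey
from ligsieve.processing_filters import PocketRecord

RMSD_GATE = 3.5
CLUSTER_THRESHOLD = 10.0


@dataclass
class Superposition:
    rotation: np.ndarray      # 3x3, det = +1
    translation: np.ndarray   # 3-vector, Å
    rmsd: float
    n_matched: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class LigandCluster:
    cluster_id: int
    members: list[tuple[str, str]]            # (pdb_id, ligand_uid)
    centroids: list[np.ndarray]


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filter mode

def remove_subsumed_fragments(pockets: list[PocketRecord],
                              graphs: dict[str, "object"],
                              log: list[str] | None = None,
                              ) -> list[PocketRecord]:
    """Drop ligands that are strict fragments of a larger covalent unit.

    A candidate is removed when its residue set is a strict subset of the
    connected component (in the non-protein connectivity graph) that
    contains it -- i.e. it is covalently bonded to additional non-protein
    residues outside itself, so some larger assembly is the real ligand.
    """
    import networkx as nx
    log = log if log is not None else []
    kept = []
    for rec in pockets:
        g = graphs.get(rec.pdb_id)
        residues = set(rec.candidate.residues)
        subsumed = False
        if g is not None:
            nodes = set(g.nodes)
            anchor = next((r for r in residues if r in nodes), None)
            if anchor is not None:
                component = nx.node_connected_component(g, anchor)
                if residues < set(component):
                    subsumed = True
        if subsumed:
            log.append(f"{rec.pdb_id}\tSUBSUMED_FRAGMENT\t{rec.ligand_uid}\t"
                       "part of a larger covalent ligand; removed")
        else:
            kept.append(rec)
    return kept


def _dedup_key(rec: PocketRecord, structure: Structure | None) -> tuple:
    cand = rec.candidate
    if cand.kind == "small_molecule":
        return ("mol",) + tuple(sorted({r.comp_id for r in cand.residues}))
    # chain ligands: equivalent copies share an entity id
    if structure is not None:
        ent = structure.entity_of_chain(cand.residues[0].chain)
        if ent is not None:
            return ("ent", ent)
    return ("chain", tuple(sorted({r.comp_id for r in cand.residues})))


def deduplicate_filter_mode(pockets: list[PocketRecord],
                            structure: Structure | None = None,
                            log: list[str] | None = None,
                            ) -> list[PocketRecord]:
    """One ligand per unique structure: the copy with most pocket residues.

    Small-molecule copies are grouped by component code(s); chain ligands
    by their entity.  Ties go to the lexicographically first (chain,
    residue number).
    """
    log = log if log is not None else []
    groups: dict[tuple, list[PocketRecord]] = {}
    order: list[tuple] = []
    for rec in pockets:
        key = _dedup_key(rec, structure)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(rec)
    selected = []
    for key in order:
        group = groups[key]
        best = min(group, key=lambda r: (
            -r.residue_count,
            r.candidate.residues[0].chain,
            r.candidate.residues[0].auth_seq))
        for rec in group:
            if rec is not best:
                log.append(f"{rec.pdb_id}\tDEDUPLICATED\t{rec.ligand_uid}\t"
                           f"equivalent to {best.ligand_uid} "
                           f"({rec.residue_count} <= {best.residue_count} "
                           "nearby residues)")
        selected.append(best)
    return selected


# ---------------------------------------------------------------------------
# superposition (cluster mode)

def kabsch_superpose(mobile: np.ndarray,
                     reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of *mobile* onto *reference*.

    Classic SVD solution of the orthogonal Procrustes problem with the
    proper-rotation (det = +1) correction; both inputs are (n, 3) arrays
    of paired coordinates, n >= 3.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 \
            or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise AlignmentError("need matching (n>=3, 3) coordinate arrays")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = rc - rotation @ mc
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return Superposition(rotation=rotation, translation=translation,
                         rmsd=rmsd, n_matched=mobile.shape[0])


def _ca_map(structure: Structure, chains: set[str]) -> dict[tuple, np.ndarray]:
    out = {}
    for a in structure.atoms:
        if a.atom_name == "CA" and a.auth_chain in chains \
                and not a.is_hydrogen:
            out[(a.auth_chain, a.auth_seq, a.ins_code)] = np.array(a.xyz)
    return out


def superpose_to_reference(mobile: Structure,
                           reference: Structure,
                           mobile_chains: set[str],
                           reference_chains: set[str],
                           rmsd_gate: float = RMSD_GATE,
                           log: list[str] | None = None,
                           ) -> Optional[Superposition]:
    """Superpose *mobile* onto *reference* on shared C-alpha atoms.

    Residues are paired by (auth chain, auth residue number) identity; only
    the given chains (those in the vicinity of at least one ligand) enter
    the fit.  Returns None -- with a logged warning -- when the alignment
    fails the RMSD gate; raises :class:`AlignmentError` when fewer than
    three C-alpha pairs exist.
    """
    log = log if log is not None else []
    m = _ca_map(mobile, mobile_chains)
    r = _ca_map(reference, reference_chains)
    shared = sorted(set(m) & set(r))
    if len(shared) < 3:
        raise AlignmentError(
            f"{mobile.pdb_id}: only {len(shared)} paired C-alpha atoms "
            f"with reference {reference.pdb_id}")
    sup = kabsch_superpose(np.array([m[k] for k in shared]),
                           np.array([r[k] for k in shared]))
    if sup.rmsd > rmsd_gate:
        log.append(f"{mobile.pdb_id}\tRMSD_EXCLUDED\t-\talignment RMSD "
                   f"{sup.rmsd:.2f} Å > {rmsd_gate} Å vs "
                   f"{reference.pdb_id}; structure excluded")
        return None
    return sup


def ligand_centroid(pocket: PocketRecord, structure: Structure,
                    superposition: Superposition | None = None) -> np.ndarray:
    """Unweighted mean of the ligand's heavy-atom coordinates (in Å)."""
    from ligsieve.enumeration import heavy_atoms_of
    atoms = heavy_atoms_of(structure, pocket.candidate.residues)
    if not atoms:
        raise ValueError(f"{pocket.ligand_uid}: no heavy atoms")
    coords = np.array([a.xyz for a in atoms], dtype=float)
    if superposition is not None:
        coords = superposition.apply(coords)
    return coords.mean(axis=0)


def cluster_centroids(centroids: Sequence[np.ndarray],
                      members: Sequence[tuple[str, str]] | None = None,
                      threshold: float = CLUSTER_THRESHOLD,
                      linkage: str = "complete") -> list[LigandCluster]:
    """Group ligand centroids by agglomerative clustering.

    Complete linkage with a distance threshold guarantees the stated
    property literally: no two members of one cluster are separated by
    more than *threshold* Å.  The threshold boundary is inclusive (pairs
    exactly at the threshold may merge).  Clusters are labelled 0, 1, ...
    in order of their first member.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("need at least one 3-D centroid")
    if members is None:
        members = [("", str(i)) for i in range(len(pts))]
    if len(pts) == 1:
        return [LigandCluster(0, [tuple(members[0])], [pts[0]])]
    model = AgglomerativeClustering(
        n_clusters=None,
        distance_threshold=float(np.nextafter(threshold, np.inf)),
        linkage=linkage)
    raw = model.fit_predict(pts)
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel)
    clusters: dict[int, LigandCluster] = {}
    for i, lab in enumerate(raw):
        cid = relabel[lab]
        cl = clusters.setdefault(cid, LigandCluster(cid, [], []))
        cl.members.append(tuple(members[i]))
        cl.centroids.append(pts[i])
    return [clusters[c] for c in sorted(clusters)]


def write_cluster_report(clusters: Iterable[LigandCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tpdb_id\tligand_uid\tcentroid_x\tcentroid_y\t"
                 "centroid_z\n")
        for cl in clusters:
            for (pdb_id, uid), cen in zip(cl.members, cl.centroids):
                fh.write(f"{cl.cluster_id}\t{pdb_id}\t{uid}\t"
                         f"{cen[0]:.3f}\t{cen[1]:.3f}\t{cen[2]:.3f}\n")


# ---------------------------------------------------------------------------
# summary output

SUMMARY_COLUMNS = ["pdb_id", "ligand_file", "ligand_uid", "ligand_kind",
                   "resolution", "uniprot", "query_chains", "contact_chains",
                   "n_nearby_residues", "flags", "cluster_id"]


def write_summary(rows: Iterable[dict], path) -> None:
    """Tab-separated summary of all selected ligands (schema fixed)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in SUMMARY_COLUMNS)
                     + "\n")


def summary_row(pocket: PocketRecord, structure: Structure, uniprot: str,
                query_chains: Iterable[str], resolution: float,
                cluster_id: Optional[int] = None) -> dict:
    cand = pocket.candidate
    return {
        "pdb_id": pocket.pdb_id or structure.pdb_id,
        "ligand_file": pocket.ligand_file,
        "ligand_uid": pocket.ligand_uid,
        "ligand_kind": cand.kind,
        "resolution": f"{resolution:.2f}",
        "uniprot": uniprot,
        "query_chains": ",".join(sorted(query_chains)),
        "contact_chains": ",".join(pocket.contact_chains),
        "n_nearby_residues": pocket.residue_count,
        "flags": ",".join(sorted(cand.flags)) or "-",
        "cluster_id": "" if cluster_id is None else cluster_id,
    }
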