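"""End-to-end orchestration: mapping → enumeration → processing → selection.

The pipeline consumes a query file (one UniProt accession per line), a
directory of mmCIF files and the reference tables, and writes -- under a
single run directory -- the per-ligand PDB files, the pocket info file,
the summary TSV, a cluster report in *cluster* mode, an event log and a
MANIFEST.  Per-PDB results are cached as JSON state files, so a rerun on
the same output directory skips already-processed entries.

A stage failure on one PDB entry is logged and skips that entry without
aborting the run.
"""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ligsieve import mmcif_model, enumeration, processing_filters, selection
from ligsieve.mmcif_model import Structure, effective_resolution
from ligsieve.query_mapping import (
    ReferenceTables,
    load_reference_tables,
    map_queries,
    read_sifts_table,
)


@dataclass
class RunConfig:
    queries_file: str
    cif_dir: str
    out_dir: str
    max_resolution: float = 3.0
    mode: str = "filter"                    # "filter" | "cluster"
    sifts: str = ""
    bird: str = ""
    counts: str = ""
    exclusion: str = ""
    keep: str = ""
    aliases: str = ""
    uniprot_lengths: str = ""
    code_map: str = ""
    pocket_cutoff: float = processing_filters.POCKET_CUTOFF
    frequent_threshold: int = enumeration.FREQUENT_LIGAND_THRESHOLD
    min_heavy_atoms: int = enumeration.MIN_HEAVY_ATOMS
    max_copies: int = enumeration.MAX_COPIES
    rmsd_gate: float = selection.RMSD_GATE
    cluster_threshold: float = selection.CLUSTER_THRESHOLD
    peptide_alpha: float = enumeration.PEPTIDE_ALPHA
    peptide_beta: float = enumeration.PEPTIDE_BETA
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("filter", "cluster"):
            raise ValueError(f"mode must be 'filter' or 'cluster', "
                             f"got {self.mode!r}")
        for name in ("max_resolution", "pocket_cutoff", "rmsd_gate",
                     "cluster_threshold", "peptide_alpha", "peptide_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @staticmethod
    def from_scenario_dirs(queries_file, cif_dir, table_dir, out_dir,
                           mode="filter", max_resolution=3.0,
                           seed: int = 0) -> "RunConfig":
        t = Path(table_dir)
        return RunConfig(
            queries_file=str(queries_file), cif_dir=str(cif_dir),
            out_dir=str(out_dir), max_resolution=max_resolution, mode=mode,
            sifts=str(t / "sifts.tsv"), bird=str(t / "bird.tsv"),
            counts=str(t / "counts.tsv"), exclusion=str(t / "exclusion.txt"),
            keep=str(t / "keep.txt"), aliases=str(t / "aliases.tsv"),
            uniprot_lengths=str(t / "uniprot_lengths.tsv"), seed=seed)


@dataclass
class RunResult:
    out_dir: Path
    summary_rows: list[dict]
    clusters: dict[str, list[selection.LigandCluster]]
    n_processed: int
    n_skipped: int
    events: list[tuple[str, str]]           # (stage, tsv event line)

    @property
    def summary_file(self) -> Path:
        return self.out_dir / "summary.tsv"

    def labels_by_pdb(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        from ligsieve.evaluation import canonical_label
        for row in self.summary_rows:
            uid = row["ligand_uid"]
            label = canonical_label(
                uid if uid.lower().startswith("chain-")
                else uid.split(".")[0])
            out.setdefault(row["pdb_id"], []).append(label)
        return out


class _EventLog:
    def __init__(self):
        self.events: list[tuple[str, str]] = []

    def stage_list(self, stage: str) -> list[str]:
        return _StageList(self, stage)

    def add(self, stage: str, line: str) -> None:
        self.events.append((stage, line))


class _StageList(list):
    """A list proxy that mirrors appended event lines into the global log."""

    def __init__(self, log: _EventLog, stage: str):
        super().__init__()
        self._log = log
        self._stage = stage

    def append(self, line: str) -> None:
        super().append(line)
        self._log.add(self._stage, line)


def _process_entry(structure: Structure, query: str, query_chains: set[str],
                   refs: ReferenceTables, config: RunConfig,
                   log: _EventLog) -> dict:
    """Run enumeration + processing on one structure; return cached state."""
    pdb_id = structure.pdb_id
    structure = mmcif_model.resolve_altlocs(structure)
    if refs.code_map or any(len(a.comp_id) == 5 for a in structure.atoms):
        structure = mmcif_model.shorten_ligand_codes(structure, refs.code_map)
    graph = enumeration.build_connectivity_graph(structure)
    for lig_res, prot_res, atoms in enumeration.detect_protein_covalent_links(
            structure, graph):
        log.add("retrieval", f"{pdb_id}\tCOVALENT_LINK\t{lig_res.label()}\t"
                f"bonded to {prot_res.label()} via "
                f"{atoms[0]}-{atoms[1]}")

    if not processing_filters.require_query_chain(structure, query,
                                                  refs.aliases):
        log.add("processing", f"{pdb_id}\tQUERY_ABSENT\t-\tquery {query} "
                "not referenced by any chain; entry dropped")
        return {"pdb_id": pdb_id, "dropped": "query-absent"}

    enum_log = log.stage_list("enumeration")
    candidates = enumeration.enumerate_candidates(
        structure, graph, refs, log=enum_log,
        alpha=config.peptide_alpha, beta=config.peptide_beta)
    candidates = enumeration.apply_enumeration_filters(
        candidates, refs.counts, refs.keep, enum_log, pdb_id,
        config.frequent_threshold, config.min_heavy_atoms, config.max_copies)

    proc_log = log.stage_list("processing")
    candidates = processing_filters.filter_exclusion_list(
        candidates, refs.exclusion, proc_log, pdb_id)
    pockets = processing_filters.pocket_gate(
        candidates, structure, query_chains, config.pocket_cutoff, proc_log)

    sel_log = log.stage_list("selection")
    _, protein_chains = enumeration.classify_polymer_chains(structure, refs)
    lig_graph = enumeration.ligand_space_graph(structure, graph,
                                               protein_chains)
    pockets = selection.remove_subsumed_fragments(
        pockets, {pdb_id: lig_graph}, sel_log)
    if config.mode == "filter":
        pockets = selection.deduplicate_filter_mode(pockets, structure,
                                                    sel_log)
    if not pockets:
        log.add("selection", f"{pdb_id}\tLIGAND_FREE\t-\tno ligands survive "
                "filtering")
    return {"structure": structure, "pockets": pockets, "pdb_id": pdb_id}


def _pocket_state(pockets, structure, query, query_chains, resolution):
    rows = []
    for p in pockets:
        rows.append(selection.summary_row(p, structure, query, query_chains,
                                          resolution))
    return rows


def run_pipeline(config: RunConfig) -> RunResult:
    config.validate()
    out = Path(config.out_dir)
    (out / "ligands").mkdir(parents=True, exist_ok=True)
    state_dir = out / "state"
    state_dir.mkdir(exist_ok=True)
    log = _EventLog()

    with open(config.queries_file) as fh:
        queries = [ln.strip() for ln in fh
                   if ln.strip() and not ln.startswith("#")]
    refs = load_reference_tables(
        bird=config.bird, counts=config.counts, exclusion=config.exclusion,
        keep=config.keep,
        uniprot_lengths=config.uniprot_lengths or None,
        aliases=config.aliases or None,
        code_map=config.code_map or None)
    sifts = read_sifts_table(config.sifts)

    cif_dir = Path(config.cif_dir)
    cif_index = {p.stem.lower(): p for p in sorted(cif_dir.glob("*.cif"))}
    parsed: dict[str, Structure] = {}

    def resolver(pdb_id: str) -> Optional[Structure]:
        pdb_id = pdb_id.lower()
        if pdb_id in parsed:
            return parsed[pdb_id]
        path = cif_index.get(pdb_id)
        if path is None:
            return None
        try:
            st = mmcif_model.parse_mmcif(path)
        except mmcif_model.MmcifParseError as exc:
            log.add("retrieval", f"{pdb_id}\tPARSE_ERROR\t-\t{exc}")
            return None
        parsed[pdb_id] = st
        return st

    mapping = map_queries(queries, sifts, refs.aliases, resolver,
                          config.max_resolution)
    for pdb_id, reason in mapping.exclusions:
        log.add("retrieval", f"{pdb_id}\tEXCLUDED\t-\t{reason}")

    summary_rows: list[dict] = []
    clusters: dict[str, list[selection.LigandCluster]] = {}
    n_processed = n_skipped = 0

    for query in mapping.associations:
        assocs = sorted(mapping.associations[query],
                        key=lambda a: a.pdb_id.lower())
        query_pockets: list[tuple] = []     # (pdb, structure, pocket, row)
        pending_state: dict[Path, list[dict]] = {}
        for assoc in assocs:
            pdb_id = assoc.pdb_id
            state_file = state_dir / f"{query}_{pdb_id}.json"
            if state_file.exists():
                cached = json.loads(state_file.read_text())
                log.add("retrieval", f"{pdb_id}\tSKIPPED\t-\talready "
                        "processed; using cached results")
                summary_rows.extend(cached["rows"])
                n_skipped += 1
                continue
            try:
                structure = resolver(pdb_id)
                result = _process_entry(structure, query,
                                        set(assoc.chains), refs, config, log)
            except Exception as exc:   # keep batch running
                log.add("error", f"{pdb_id}\tSTAGE_ERROR\t-\t{exc}")
                continue
            n_processed += 1
            if "pockets" not in result:
                state_file.write_text(json.dumps({"rows": []}))
                continue
            structure = result["structure"]
            pockets = result["pockets"]
            rows = _pocket_state(pockets, structure, query,
                                 assoc.chains, assoc.resolution)
            for pocket, row in zip(pockets, rows):
                keys = {(r.chain, r.auth_seq, r.ins_code)
                        for r in pocket.candidate.residues}
                mmcif_model.write_pdb_subset(
                    structure,
                    lambda a, keys=keys: (a.auth_chain, a.auth_seq,
                                          a.ins_code) in keys,
                    out / "ligands" / pocket.ligand_file)
                query_pockets.append((pdb_id, structure, pocket, row))
            summary_rows.extend(rows)
            pending_state[state_file] = rows

        if config.mode == "cluster" and query_pockets:
            clusters[query] = _cluster_query(query, query_pockets, config,
                                             log, out)
        # state written after clustering so cached rows keep cluster ids
        for state_file, rows in pending_state.items():
            state_file.write_text(json.dumps({"rows": rows}))

    _write_pockets_from_rows(summary_rows, out)
    selection.write_summary(summary_rows, out / "summary.tsv")
    _write_log(log, out / "log.tsv")
    _write_manifest_file(out, config)
    return RunResult(out_dir=out, summary_rows=summary_rows,
                     clusters=clusters, n_processed=n_processed,
                     n_skipped=n_skipped, events=log.events)


def _write_pockets_from_rows(rows: list[dict], out: Path) -> None:
    # pocket info file distilled from summary rows (survives cached reruns)
    with open(out / "pocket_info.tsv", "w") as fh:
        fh.write("ligand_file\tpdb_id\tligand_uid\tresidue_count\t"
                 "contact_chains\n")
        for row in rows:
            fh.write(f"{row['ligand_file']}\t{row['pdb_id']}\t"
                     f"{row['ligand_uid']}\t{row['n_nearby_residues']}\t"
                     f"{row['contact_chains']}\n")


def _cluster_query(query: str, query_pockets: list[tuple],
                   config: RunConfig, log: _EventLog,
                   out: Path) -> list[selection.LigandCluster]:
    """Superpose all structures of one query and cluster ligand centroids."""
    by_pdb: dict[str, list[tuple]] = {}
    structures: dict[str, Structure] = {}
    for pdb_id, structure, pocket, row in query_pockets:
        by_pdb.setdefault(pdb_id, []).append((pocket, row))
        structures[pdb_id] = structure
    order = sorted(by_pdb, key=str.lower)    # reference: first name-sorted
    ref_pdb = order[0]
    ref_chains = _vicinity_chains(by_pdb[ref_pdb])
    sel_log = log.stage_list("selection")
    centroids, members, member_rows = [], [], []
    for pdb_id in order:
        chains = _vicinity_chains(by_pdb[pdb_id])
        if pdb_id == ref_pdb:
            sup = None
        else:
            try:
                sup = selection.superpose_to_reference(
                    structures[pdb_id], structures[ref_pdb], chains,
                    ref_chains, config.rmsd_gate, sel_log)
            except selection.AlignmentError as exc:
                log.add("selection", f"{pdb_id}\tALIGNMENT_ERROR\t-\t{exc}")
                continue
            if sup is None:     # RMSD gate: structure dropped with warning
                for _, row in by_pdb[pdb_id]:
                    row["cluster_id"] = ""
                continue
        for pocket, row in by_pdb[pdb_id]:
            centroids.append(selection.ligand_centroid(
                pocket, structures[pdb_id], sup))
            members.append((pdb_id, pocket.ligand_uid))
            member_rows.append(row)
    if not centroids:
        return []
    cls = selection.cluster_centroids(centroids, members,
                                      config.cluster_threshold)
    uid_to_cluster = {m: c.cluster_id for c in cls for m in c.members}
    for (pdb_id, uid), row in zip(members, member_rows):
        row["cluster_id"] = uid_to_cluster[(pdb_id, uid)]
    selection.write_cluster_report(cls, out / f"clusters_{query}.tsv")
    return cls


def _vicinity_chains(pocket_rows: list[tuple]) -> set[str]:
    chains: set[str] = set()
    for pocket, _ in pocket_rows:
        chains |= set(pocket.contact_chains)
    return chains


def _write_log(log: _EventLog, path: Path) -> None:
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with open(path, "a") as fh:
        for stage, line in log.events:
            fh.write(f"{stamp}\t{stage}\t{line}\n")


def _write_manifest_file(out: Path, config: RunConfig) -> None:
    entries = sorted(str(p.relative_to(out))
                     for p in out.rglob("*") if p.is_file()
                     and p.name != "MANIFEST")
    with open(out / "MANIFEST", "w") as fh:
        fh.write(f"mode\t{config.mode}\n")
        for e in entries:
            fh.write(f"file\t{e}\n")
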