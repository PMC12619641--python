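"""UniProt-query to PDB-entry mapping and reference-table loading.

A SIFTS-style table associates (pdb_id, chain) pairs with UniProt
accessions.  Queries and table entries are both remediated through a
secondary→primary accession alias table before matching, so entries
deposited under outdated accessions are still found.  Entries without any
reported resolution, or above the user's resolution cutoff, are excluded
with a logged reason.

Reference tables (all plain text, see the schemas in the README):

==================  =========================================================
sifts               TSV ``pdb_id<TAB>chain<TAB>uniprot``
aliases             TSV ``secondary<TAB>primary``
bird                TSV ``prd_id<TAB>sequence<TAB>pdb_ids(comma-sep)``
counts              TSV ``code<TAB>n_pdbs`` (PDB-entry occurrence per code)
keep / exclusion    one ligand code per line, ``#`` comments
uniprot_lengths     TSV ``accession<TAB>sequence_length`` (optional)
==================  =========================================================
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional

from ligsieve.mmcif_model import Structure, effective_resolution


@dataclass(frozen=True)
class SiftsRow:
    pdb_id: str
    chain: str
    uniprot: str


class AccessionAliasTable:
    """Secondary→primary UniProt accession map; remediation is idempotent."""

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for sec, pri in (mapping or {}).items():
            self._map[sec.strip().upper()] = pri.strip().upper()

    def remediate(self, accession: str) -> str:
        acc = accession.strip().upper()
        seen = {acc}
        while acc in self._map and self._map[acc] != acc:
            acc = self._map[acc]
            if acc in seen:          # defensive: break alias cycles
                break
            seen.add(acc)
        return acc

    def __len__(self) -> int:
        return len(self._map)


@dataclass(frozen=True)
class BirdEntry:
    prd_id: str
    sequence: str
    pdb_ids: frozenset[str]


@dataclass
class PdbAssociation:
    pdb_id: str
    chains: list[str]
    resolution: float


@dataclass
class QueryMapping:
    """query accession → retained PDB associations, plus exclusion log."""
    associations: dict[str, list[PdbAssociation]] = field(default_factory=dict)
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (pdb, reason)

    def pdb_ids(self, query: str) -> list[str]:
        return [a.pdb_id for a in self.associations.get(query.upper(), [])]


@dataclass
class ReferenceTables:
    bird: list[BirdEntry]
    counts: dict[str, int]
    exclusion: set[str]
    keep: set[str]
    uniprot_lengths: dict[str, int] = field(default_factory=dict)
    aliases: AccessionAliasTable = field(default_factory=AccessionAliasTable)
    code_map: dict[str, str] = field(default_factory=dict)  # 5-char → short


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# file readers

def _read_lines(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh]


def _read_code_set(path: str | os.PathLike) -> set[str]:
    out = set()
    for ln in _read_lines(path):
        ln = ln.split("#", 1)[0].strip()
        if ln:
            out.add(ln.upper())
    return out


def read_sifts_table(path: str | os.PathLike) -> list[SiftsRow]:
    rows = []
    for i, ln in enumerate(_read_lines(path)):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if i == 0 and parts[0].lower() in ("pdb_id", "pdb"):
            continue
        if len(parts) < 3:
            continue
        rows.append(SiftsRow(pdb_id=parts[0].strip().lower(),
                             chain=parts[1].strip(),
                             uniprot=parts[2].strip().upper()))
    return rows


def read_alias_table(path: str | os.PathLike) -> AccessionAliasTable:
    mapping = {}
    for ln in _read_lines(path):
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) >= 2 and parts[0].lower() != "secondary":
            mapping[parts[0]] = parts[1]
    return AccessionAliasTable(mapping)


def read_bird_table(path: str | os.PathLike) -> list[BirdEntry]:
    entries = []
    for ln in _read_lines(path):
        ln = ln.rstrip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if parts[0].lower() == "prd_id":
            continue
        seq = parts[1].strip().upper() if len(parts) > 1 else ""
        pdbs = frozenset(p.strip().lower() for p in parts[2].split(",")
                         if p.strip()) if len(parts) > 2 else frozenset()
        entries.append(BirdEntry(prd_id=parts[0].strip(), sequence=seq,
                                 pdb_ids=pdbs))
    return entries


def read_counts_table(path: str | os.PathLike) -> dict[str, int]:
    out: dict[str, int] = {}
    for ln in _read_lines(path):
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) >= 2 and parts[0].lower() != "code":
            out[parts[0].strip().upper()] = int(parts[1])
    return out


def read_lengths_table(path: str | os.PathLike) -> dict[str, int]:
    out: dict[str, int] = {}
    for ln in _read_lines(path):
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) >= 2 and parts[0].lower() != "accession":
            out[parts[0].strip().upper()] = int(parts[1])
    return out


def read_code_map(path: str | os.PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    for ln in _read_lines(path):
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) >= 2 and len(parts[0]) == 5:
            out[parts[0].strip().upper()] = parts[1].strip().upper()
    return out


def load_reference_tables(bird: str | os.PathLike,
                          counts: str | os.PathLike,
                          exclusion: str | os.PathLike,
                          keep: str | os.PathLike,
                          uniprot_lengths: str | os.PathLike | None = None,
                          aliases: str | os.PathLike | None = None,
                          code_map: str | os.PathLike | None = None,
                          ) -> ReferenceTables:
    """Load every auxiliary table the pipeline needs.

    Ligand codes are uppercased and deduplicated; an overlap between the
    keep-list and the exclusion list is a configuration error (a code cannot
    be both a legitimate frequent ligand and an additive to discard).
    """
    excl = _read_code_set(exclusion)
    keep_set = _read_code_set(keep)
    overlap = sorted(excl & keep_set)
    if overlap:
        raise ConfigurationError(
            "codes present in both keep and exclusion lists: "
            + ", ".join(overlap))
    return ReferenceTables(
        bird=read_bird_table(bird),
        counts=read_counts_table(counts),
        exclusion=excl,
        keep=keep_set,
        uniprot_lengths=(read_lengths_table(uniprot_lengths)
                         if uniprot_lengths else {}),
        aliases=(read_alias_table(aliases) if aliases
                 else AccessionAliasTable()),
        code_map=(read_code_map(code_map) if code_map else {}),
    )


# ---------------------------------------------------------------------------
# query mapping

def map_queries(queries: Iterable[str],
                sifts: Iterable[SiftsRow],
                aliases: AccessionAliasTable,
                structures: Callable[[str], Optional[Structure]],
                max_resolution: float) -> QueryMapping:
    """Associate each query accession with the PDB entries that contain it.

    A PDB entry is associated with a query iff some chain maps -- after
    alias remediation of both the query and the table accession -- to the
    query's primary accession.  Entries without resolution data, or with an
    effective resolution above *max_resolution*, are excluded and the
    reason logged in the returned mapping.  A chain mapped to several
    accessions (chimera) matches if any of them is the query.
    """
    if max_resolution <= 0:
        raise ValueError("max_resolution must be positive")
    queries = list(queries)
    if not queries:
        raise ValueError("no queries given")

    by_pdb: dict[str, list[SiftsRow]] = {}
    for row in sifts:
        by_pdb.setdefault(row.pdb_id, []).append(row)

    result = QueryMapping()
    for query in queries:
        primary = aliases.remediate(query)
        result.associations.setdefault(primary, [])
        hit_chains: dict[str, list[str]] = {}
        for pdb_id, rows in by_pdb.items():
            chains = sorted({r.chain for r in rows
                             if aliases.remediate(r.uniprot) == primary})
            if chains:
                hit_chains[pdb_id] = chains
        for pdb_id in sorted(hit_chains):
            st = structures(pdb_id)
            if st is None:
                result.exclusions.append((pdb_id, "structure unavailable"))
                continue
            res = effective_resolution(st)
            if res is None:
                result.exclusions.append((pdb_id, "no resolution data"))
                continue
            if res > max_resolution:
                result.exclusions.append(
                    (pdb_id, f"resolution above cutoff ({res:.2f} > "
                             f"{max_resolution:.2f})"))
                continue
            result.associations[primary].append(
                PdbAssociation(pdb_id=pdb_id, chains=hit_chains[pdb_id],
                               resolution=res))
    return result
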