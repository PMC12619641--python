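"""Precision/recall benchmarking of detected vs. curated true-ligand sets.

Per PDB entry, with detected set D and true set T:

    precision = |D ∩ T| / |D|     (undefined when D is empty)
    recall    = |D ∩ T| / |T|     (undefined when T is empty)

Reporting precision as 0 when nothing is detected would confuse a recall
failure with misidentification, so both quantities are carried as explicit
*undefined* markers (``None``) and excluded from the means.  The one
exception: D and T both empty is a perfect match, precision = recall = 1.

Comparator-tool label dialects are normalized to a common vocabulary:
component codes for small molecules and ``chain-X`` for chain-encoded
(multi-residue) ligands.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


def canonical_label(label: str) -> str:
    """Canonical form: uppercase codes; ``chain-X`` with uppercase chain."""
    label = label.strip()
    if label.upper().startswith("CHAIN-"):
        return "chain-" + label[6:].upper()
    return label.upper()


@dataclass(frozen=True)
class LigandLabelSet:
    pdb_id: str
    labels: frozenset[str]

    @staticmethod
    def make(pdb_id: str, labels: Iterable[str]) -> "LigandLabelSet":
        return LigandLabelSet(pdb_id=pdb_id.lower(),
                              labels=frozenset(canonical_label(l)
                                               for l in labels))


@dataclass
class PdbScore:
    pdb_id: str
    precision: Optional[float]
    recall: Optional[float]
    n_detected: int
    n_true: int


@dataclass
class EvaluationResult:
    scores: list[PdbScore]
    mean_precision: Optional[float]
    mean_recall: Optional[float]
    sd_precision: Optional[float]
    sd_recall: Optional[float]
    n_pdbs: int
    n_undefined_precision: int
    n_undefined_recall: int

    @property
    def balanced_accuracy(self) -> Optional[float]:
        if self.mean_precision is None or self.mean_recall is None:
            return None
        return (self.mean_precision + self.mean_recall) / 2.0


def score_pdb(detected: LigandLabelSet,
              truth: LigandLabelSet) -> tuple[Optional[float], Optional[float]]:
    """Per-entry precision and recall with the undefined-value conventions."""
    if detected.pdb_id != truth.pdb_id:
        raise ValueError(f"pdb_id mismatch: {detected.pdb_id} vs "
                         f"{truth.pdb_id}")
    d, t = detected.labels, truth.labels
    if not d and not t:
        return 1.0, 1.0
    inter = len(d & t)
    precision = inter / len(d) if d else None
    recall = inter / len(t) if t else None
    return precision, recall


def aggregate(pairs: Iterable[tuple[LigandLabelSet, LigandLabelSet]]
              ) -> EvaluationResult:
    """Mean precision/recall over all entries, ignoring undefined values."""
    scores = []
    for detected, truth in pairs:
        p, r = score_pdb(detected, truth)
        scores.append(PdbScore(pdb_id=detected.pdb_id, precision=p, recall=r,
                               n_detected=len(detected.labels),
                               n_true=len(truth.labels)))
    if not scores:
        raise ValueError("no PDB entries to aggregate")
    precs = [s.precision for s in scores if s.precision is not None]
    recs = [s.recall for s in scores if s.recall is not None]

    def mean(vals):
        return sum(vals) / len(vals) if vals else None

    def sd(vals):     # sample SD (n-1)
        if len(vals) < 2:
            return 0.0 if vals else None
        return statistics.stdev(vals)

    return EvaluationResult(
        scores=scores,
        mean_precision=mean(precs), mean_recall=mean(recs),
        sd_precision=sd(precs), sd_recall=sd(recs),
        n_pdbs=len(scores),
        n_undefined_precision=len(scores) - len(precs),
        n_undefined_recall=len(scores) - len(recs),
    )


# ---------------------------------------------------------------------------
# label-dialect normalization

class LabelParseError(ValueError):
    pass


def normalize_tool_label(raw: str, dialect: str,
                         valid: Optional[bool] = None) -> Optional[str]:
    """Convert a comparator tool's ligand label to the common vocabulary.

    Dialects:

    * ``proteinsplus`` -- ``residueCode_chain_residueNumber``; more than
      three underscores means a multi-residue (chain) ligand.
    * ``moad`` -- ``residueCode:chain:residueNumber``; more than four
      characters before the first colon means a chain ligand.  Entries not
      marked valid (pass ``valid=False``) are dropped (returns None).
    * ``biolip2`` -- small molecules by code; peptide/dna ligands already
      arrive as ``chain-X``.
    * ``ligsieve`` -- this package's own uid scheme (``CODE.A.1``,
      ``CODE1-CODE2.A.1`` or ``chain-X``).
    """
    raw = raw.strip()
    if not raw:
        raise LabelParseError("empty ligand label")
    dialect = dialect.lower()
    if dialect == "proteinsplus":
        parts = raw.split("_")
        if len(parts) < 3:
            raise LabelParseError(f"unparseable ProteinsPlus label: {raw!r}")
        if raw.count("_") > 3:
            return canonical_label(f"chain-{parts[1]}")
        return parts[0].upper()
    if dialect == "moad":
        if valid is False:
            return None
        head, _, rest = raw.partition(":")
        if not rest:
            raise LabelParseError(f"unparseable MOAD label: {raw!r}")
        if len(head) > 4:
            chain = rest.split(":")[0]
            return canonical_label(f"chain-{chain}")
        return head.upper()
    if dialect == "biolip2":
        return canonical_label(raw)
    if dialect == "ligsieve":
        if raw.lower().startswith("chain-"):
            return canonical_label(raw)
        return raw.split(".")[0].upper()
    raise LabelParseError(f"unknown dialect: {dialect!r}")


def read_truth_table(path) -> dict[str, set[str]]:
    """TSV ``pdb_id<TAB>label<TAB>is_true_ligand{0,1}`` → pdb → true labels."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if parts[0].lower() == "pdb_id":
                continue
            pdb = parts[0].lower()
            out.setdefault(pdb, set())
            if len(parts) >= 3 and parts[2].strip() == "1":
                out[pdb].add(canonical_label(parts[1]))
            elif len(parts) == 2 and parts[1].strip():
                out[pdb].add(canonical_label(parts[1]))
    return out
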