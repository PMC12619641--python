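# Methods

This note documents the model of ligand annotation the package implements,
the decision rules and their parameters, the numerical choices, what the
synthetic data emulate, and the known limitations.

## Structure model

An mmCIF entry is reduced to a typed structure: an ordered atom table
(auth_* and label_* identifiers, element, occupancy, alternate location,
coordinates), entities with their type and source method, chain database
references from `_struct_ref`/`_struct_ref_seq`, covalent/other
connections from `_struct_conn`, branched-entity composition from
`_pdbx_entity_branch`/`_pdbx_branch_scheme`, per-entity theoretical
one-letter sequences from `_entity_poly`, and the list of reported
resolutions. Conventions:

* only model 1 is kept for multi-model files;
* alternate locations are resolved to the highest-occupancy atom, ties
  broken by the lexicographically smallest alt-loc id (idempotent);
* the effective resolution is the maximum of the reported values —
  the conservative choice when a record carries several;
* hydrogens stay in the atom table but all size and distance computations
  use heavy atoms only;
* auth_* chain/residue identifiers are used in every user-facing output,
  matching the identifiers a PDB-format file shows; label_* identifiers
  serve only entity bookkeeping;
* legacy 5-character component codes are shortened through an explicit,
  auditable mapping table supplied as input rather than recomputed.

## Connectivity and candidate enumeration

The central data structure is an undirected residue-level connectivity
graph. Residues with consecutive author numbering in the ATOM group of
one chain are assumed bonded (the standard polymer assumption); HETATM
residues gain edges **only** from explicit `covale` records. This is what
makes ATOM/HETATM-intercalated chain ligands (cyclosporin-style cyclic
peptides) and split fragments (a carbobenzoxy group deposited apart from
its amino-acid partner) recoverable as single connected components.

Candidate routes, which partition the non-protein, non-water residues:

1. **Peptide-ligand chains.** A polymer chain is a ligand when (a) it has
   no UniProt reference (self-referenced deposition), or (b) it is a
   synthetic construct (`_entity.src_method = syn`) whose resolved length
   is ≥ α of its theoretical sequence and whose theoretical sequence is
   ≤ β of the full-length UniProt sequence, or (c) its sequence exactly
   matches a BIRD reference entry. Defaults α = 0.8, β = 0.5: a peptide
   ligand is expected to be nearly fully resolved and deliberately much
   shorter than the protein it derives from. Both are configurable; the
   thresholds are design choices quantifying an inherently qualitative
   criterion, and the conservative default keeps naturally small
   full-length proteins (a 36-residue chain covering its whole UniProt
   entry) out of the ligand set. Chains classified as ligands are
   extended with HETATM residues covalently bonded to them.
2. **Branched entities.** A sugar tree covalently attached to an
   ASN/SER/THR of a UniProt-mapped chain is a glycosylation group, not a
   ligand — unless it is BIRD-matched, in which case it is kept and
   flagged covalent so users can separate covalent from non-covalent
   binders. Unattached oligosaccharides are ligands. BIRD matching for
   branches uses the PRD→PDB association (saccharide entries carry no
   one-letter sequence) or the hyphen-joined monomer string.
3. **Connected components** of the graph restricted to non-protein
   residues that contain at least one HETATM residue become
   small-molecule candidates; multi-residue components are flagged
   `reassembled_multi_residue`.

The protein side is defined as UniProt-mapped polymer chains that fail
the peptide rules; the 20 canonical amino acids plus MSE count as protein
residues, so modified residues inside mapped chains never become
candidates. Waters are excluded outright.

Enumeration filters: component codes present in more than 250 PDB entries
are *flagged* (not removed) as probable additives unless on the curated
keep-list of legitimately common ligands (ATP, NAD, HEM, ...); candidates
with fewer than 3 heavy atoms are removed; a species with more than 10
copies in one structure is removed entirely. "Copies" counts instances
of the same component code among single-residue candidates.

## Processing filters

* **Exclusion list** — single-residue small molecules whose code is on
  the solvent/additive/salt list are removed. Multi-residue candidates
  are immune: a listed code that is merely a fragment of a larger
  covalent ligand must survive inside it.
* **Query presence** — entries whose chain references (after alias
  remediation) never resolve to the query accession are dropped.
* **Pocket gate** — a ligand survives only if at least one of its heavy
  atoms lies within 6.0 Å (boundary inclusive) of a heavy atom of a
  query-mapped chain. The stored pocket lists every polymer residue
  (any chain) with an atom in range, at residue granularity. The
  implementation uses a k-d tree but is tested for exact agreement with
  a brute-force all-pairs oracle.

## Selection

*filter* mode groups equivalent copies (small molecules by component
code(s), chain ligands by entity) and keeps the copy with the most pocket
residues, ties broken by lexicographic (chain, residue number). Before
deduplication, any candidate whose residue set is a strict subset of a
larger covalent component is removed as a subsumed fragment.

*cluster* mode superposes every structure of a query onto the reference
(first file in case-insensitive name order) with a Kabsch least-squares
fit on C-alpha atoms paired by (auth chain, auth residue number), using
only chains in the 6 Å vicinity of at least one ligand. Structures with
fit RMSD > 3.5 Å are excluded with a logged warning (their ligands are
dropped rather than reported unclustered — an explicit design choice).
Per-ligand heavy-atom centroids are then grouped by agglomerative
clustering. **Complete linkage** is the default because it makes the
stated guarantee literally true: no two members of one cluster are ever
more than the 10 Å threshold apart (average or single linkage would not
guarantee this); the linkage is configurable. The scikit-learn
`distance_threshold` is exclusive, so the threshold is passed as
`nextafter(10, +inf)` to make the boundary inclusive. Cluster labels are
renumbered by first-member order so output is permutation-stable.

## Evaluation

Per entry, precision = |D∩T|/|D| and recall = |D∩T|/|T|. An empty
denominator makes the metric *undefined* (carried as an explicit marker,
never as 0, because "nothing detected" is a recall failure, not
misidentification); both sets empty is a perfect match (precision =
recall = 1). Means are taken over defined entries only; the reported SD
is the sample standard deviation (n−1). Comparator label dialects are
normalized to a common vocabulary — component codes for small molecules,
`chain-X` for chain-encoded ligands — with the underscore-count rule for
ProteinsPlus names, the prefix-length rule for MOAD names (keeping only
entries marked valid), and pass-through for BioLiP2.

## Synthetic data

The generator emits small, syntactically complete mmCIF entries: protein
chains are ideal-geometry poly-alanine helices (with LYS/ASN side chains
where a covalent acceptor is needed), ligands are compact heavy-atom
blobs. Twelve scenarios cover the annotation situations the pipeline
must handle (see the module docstring): split-fragment reassembly,
intercalated cyclic peptides, unmapped peptide chains, covalent warheads,
N-glycosylation vs. free oligosaccharides, frequent additives, multi-copy
deduplication, small natural proteins, and a five-structure two-site
clustering set (16 ligands, sites 30 Å apart, 1 Å positional jitter,
rigid whole-structure perturbations that the superposition must undo).
Generation is fully deterministic given (scenario, seed).

What these fixtures do **not** emulate: real chemistry (bond lengths and
chemistry of the blobs are nonphysical), sequence diversity, crystal
packing, disorder, obsolete PDB entries, or the long tail of deposition
idiosyncrasies in the archive. Passing the scenario suite therefore
shows the decision logic is implemented as specified, not that every
archival corner case is covered; in particular, peptide ligands deposited
indistinguishably from natural protein fragments (hirudin-style chains
annotated with the parent protein's accession and a natural source) are
out of reach of any annotation-based rule and are a known recall
limitation on real data.

Problem sizes were chosen at desk scale — tens of residues per chain and
a handful of entries per scenario — which exercises every code path while
keeping the whole suite and the acceptance script in the seconds range.

## Other numerical choices

* Distances are minimum heavy-atom Euclidean distances; all gate
  boundaries (6 Å pocket, 10 Å clustering) are inclusive.
* Kabsch superposition uses the SVD solution with the det = +1
  correction; it is cross-checked in the tests against an independent
  quaternion (Horn) oracle to 1e-8 Å.
* Alias remediation follows chains of secondary accessions and is
  idempotent; defensive cycle-breaking guards against malformed tables.
* Reruns on the same output directory reuse per-entry JSON state files
  and skip reprocessing; cached rows retain their cluster assignments.

## Known limitations

* No bond-order or protonation chemistry; no SMILES export.
* Residue pairing for superposition is by identifier, not sequence
  alignment, so renumbered depositions of the same protein would need a
  preprocessing step.
* Obsolete/superseded PDB ids are treated as absent from the SIFTS table.
* No NMR ensemble handling (model 1 only), no assembly expansion, no
  interaction typing beyond proximity.
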