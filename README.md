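# ligsieve

Large-scale identification, curation and extraction of ligands of
pharmaceutical interest from PDBx/mmCIF protein structures.

## The problem

Most structure-mining workflows assume a ligand is a single HETATM residue
with its own component code. Real depositions are messier: peptide ligands
are stored as polymer chains (sometimes with residues split between the
ATOM and HETATM groups), apparent "ligands" such as PHQ are actually
fragments of a larger covalent assembly, oligosaccharides can be either
glycosylation decorations or genuine ligands (e.g. heparin fragments), and
solvents and crystallisation additives are annotated exactly like drugs.
Mislabelling any of these skews holo/apo classification, dataset assembly
and downstream docking or SAR studies.

`ligsieve` takes a list of UniProt accessions and a directory of mmCIF
files and returns, per structure, the set of ligands of interest — small
molecules, chain-encoded peptides, BIRD-matched molecules, free
oligosaccharides and covalent binders — together with per-ligand PDB
files, a binding-pocket report and a machine-parseable decision log.

## Method summary

Four stages, run per query accession:

1. **Mapping** — a SIFTS-style chain→UniProt table (with secondary→primary
   accession remediation) associates queries with PDB entries; entries
   without resolution data or above the user cutoff are excluded. The
   effective resolution is the highest (worst) reported value.
2. **Enumeration** — a residue-level covalent-connectivity graph is built:
   consecutive ATOM residues of a chain are implicitly bonded, HETATM
   residues only through explicit `covale` records in `_struct_conn`.
   Candidates are (i) connected components containing a HETATM residue and
   no protein residue (this reassembles split multi-residue ligands),
   (ii) polymer chains reclassified as peptide ligands (unmapped chains,
   short synthetic constructs, exact BIRD sequence matches), (iii)
   non-polymer/macrolide entities, (iv) branched entities that are not
   glycosylation groups. Codes seen in >250 PDB entries are flagged as
   probable additives unless kept by a curated keep-list (ATP and
   friends); candidates with <3 heavy atoms or >10 copies are removed.
3. **Processing** — exclusion-list removal (solvents/additives/salts),
   a check that the query protein is actually referenced by the entry, and
   a 6 Å pocket gate: a ligand survives only if a heavy atom of a
   query-mapped chain lies within 6 Å of one of its heavy atoms.
4. **Selection** — *filter* mode keeps one representative per unique
   ligand (the copy with the most pocket residues); *cluster* mode
   superposes all structures of a query onto the first file in name-sorted
   order (Kabsch fit on shared C-alpha atoms, structures with RMSD > 3.5 Å
   excluded), computes heavy-atom centroids per ligand and groups them by
   complete-linkage agglomerative clustering with a 10 Å threshold.

Benchmarking uses per-entry precision `|D∩T|/|D|` and recall `|D∩T|/|T|`
against curated true-ligand sets, with explicit *undefined* values when a
denominator is empty (and precision = recall = 1 when both sets are
empty), averaged over the defined entries only.

## Worked example

Generate a synthetic scenario (a query protein with an ATP molecule and a
peptide ligand deposited as an unmapped chain) and run the pipeline:

```bash
ligsieve fixtures --scenario S5 --out /tmp/s5
ligsieve run --queries /tmp/s5/queries.txt --cif-dir /tmp/s5/cifs \
    --out /tmp/s5/out --mode filter \
    --sifts /tmp/s5/tables/sifts.tsv --bird /tmp/s5/tables/bird.tsv \
    --counts /tmp/s5/tables/counts.tsv \
    --exclusion /tmp/s5/tables/exclusion.txt --keep /tmp/s5/tables/keep.txt \
    --aliases /tmp/s5/tables/aliases.tsv \
    --uniprot-lengths /tmp/s5/tables/uniprot_lengths.tsv
```

which prints

```
processed 1 PDB entries (0 cached), 2 ligands -> /tmp/s5/out/summary.tsv
```

`summary.tsv` then contains one row per ligand: the ATP copy
(`ATP.C.1`, kind `small_molecule`) and the peptide chain (`chain-E`, kind
`chain_peptide`), each with its resolution, query chains, contact chains
and pocket residue count. Scoring the run against the scenario's truth
table:

```bash
ligsieve evaluate --pred /tmp/s5/out/summary.tsv --truth truth.tsv
```

```
n_pdbs            1
mean precision    100.0% (SD 0.0%)
mean recall       100.0% (SD 0.0%)
balanced accuracy 100.0%
```

meaning every detected ligand is a true ligand and every true ligand was
found.

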