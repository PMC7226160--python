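# m5uevo

Comparative-genomics toolkit for the C5-uracil methyltransferase gene
families of genome-reduced bacteria (mollicutes). It classifies
flavin/folate-dependent (COG1206) homologs into the TrmFO / RlmFO /
TrmFO-like subfamilies from diagnostic residues, motifs and gene-neighborhood
conservation, and reconstructs most-parsimonious gain / loss / duplication /
pseudogenization / horizontal-transfer scenarios for each family on a rooted
species tree.

The package ships a curated reference dataset: a 39-species rooted tree with
labeled internal nodes, a species x family phyletic matrix (copy counts and
functional status), gene-neighborhood tables, empirical RNA-modification
phenotypes, and the annotated alignment reference (catalytic C51/C223,
folate triad H308/[R,K]309/N310, flavin-stacking Y343, FAD motif
`GAGx[A/S]GxE[A/V]`).

## Modules

| module | contents |
| --- | --- |
| `m5uevo.newick` | newick parser/writer, rooted `SpeciesTree` |
| `m5uevo.datamodel` | `FamilyState`, `PhyleticMatrix`, `GeneNeighborhood`, phenotypes, reference annotation |
| `m5uevo.io` | TSV/FASTA/newick I/O, packaged dataset loader with integrity checks |
| `m5uevo.classify` | global alignment (BLOSUM62, affine 11/1), residue signatures, FAD-motif scan, pseudogene detection, subfamily decision rules |
| `m5uevo.synteny` | neighborhood Jaccard scores and context profiles |
| `m5uevo.events` | binary Sankoff, Dollo, Dollo-with-transfers reconstruction, MPR enumeration, event typing, matrix counts, mutual exclusivity, genotype-phenotype checks |
| `m5uevo.simulate` | gene-content evolution simulator and planted-diagnostic protein/CDS generator |
| `m5uevo.cli` | `m5uevo` command-line interface |

## CLI

```sh
# reproduce the curated-dataset counts and consistency checks
m5uevo reproduce            # or: m5uevo reproduce --json

# reconstruct event scenarios (defaults: packaged tree/matrix, COG1206 families)
m5uevo reconstruct --mode dollo_with_transfers \
    --events-out events.tsv --report-out report.json

# classify proteins against the packaged reference
m5uevo classify --fasta proteins.faa --cds genes.fna \
    --neighborhoods hoods.tsv --out calls.tsv

# score neighborhood conservation
m5uevo synteny --neighborhoods hoods.tsv

# simulate gene-content evolution along a tree
m5uevo simulate --loss-rate 0.1 --seed 7 --matrix-out sim.tsv --events-out ev.tsv
```

Event conventions: events are annotated on edges identified by the child
node's label; the root state and the single Dollo origin are free (ancestral
presence is not an event); pseudogenes count as present for parsimony and as
nonfunctional for the mutual-exclusivity and genotype-phenotype checks.

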