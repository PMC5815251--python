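# preyweb

A toolkit for predator-diet DNA metabarcoding of arthropod gut contents:
design clade-discriminative PCR primers and predator-blocking primers
from rRNA alignments, quality-filter and demultiplex indexed amplicon
reads, cluster them into 97% OTUs, assign taxonomy by
lowest-common-ancestor consensus, and assemble bipartite predator–prey
food-web matrices with per-PCR-setting summaries. A ground-truthed
amplicon simulator makes the whole pipeline testable end to end without
any sequencing data.

## Modules

| module | what it does |
|---|---|
| `preyweb.primer_design` | alignment profiles, IUPAC consensus, exhaustive discriminative-window scan, C3-spacer blocking primers anchored on indels |
| `preyweb.read_processing` | dual-index demultiplexing (exact match, any index base < Q30 discarded), 3'-peeling quality trim, length (≥170 bp) and low-quality-fraction (<10% sub-Q30) filters |
| `preyweb.otu_clustering` | dereplication, abundance-ordered greedy centroid clustering at 97% identity (banded alignment + conservative k-mer screen), ≤10-read OTU removal |
| `preyweb.taxonomy` | neighbor-band (best-identity − ε) LCA assignment, target-clade retention (Hexapoda/Araneae) |
| `preyweb.foodweb` | sample×OTU tables → predator×prey matrices (by OTU or by species), cross-setting union with per-specimen deduplication, summary tables, rarefaction curves |
| `preyweb.synthetic_data` | predator-dominated template pools, intragenomic ITS2 variants, per-setting blocking efficiency β, error/quality models, dual 8-mer indexes |
| `preyweb.pipeline` | QC → clustering → taxonomy → food-web wiring |

## CLI

```bash
# design primers from paired clade alignments (gapped FASTA)
preyweb design --target hexapoda.afa --excluded araneae.afa \
    --min-conservation 0.9 --length 17:25 --blocking-anchor 38:42 --out candidates.tsv

# simulate a ground-truthed run (FASTQ + sample sheet + references + truth)
preyweb simulate --preset desk --seed 42 --outdir sim/

# QC: demultiplex, trim, filter
preyweb process --reads sim/reads.fastq --sheet sim/sample_sheet.tsv --outdir qc/

# pooled 97% OTU clustering
preyweb cluster --indir qc/ --identity 0.97 --min-otu-reads 11 --out otu/

# LCA taxonomy against a reference FASTA with ;tax= lineages
preyweb assign --otus otu/centroids.fasta --refs sim/references.fasta --out assign.tsv

# interaction matrices, union network, per-setting summaries
preyweb foodweb --otu-table otu/otu_table.tsv --tax assign.tsv \
    --sheet sim/sample_sheet.tsv --mode by_species --outdir web/
```

The sample sheet is TSV with columns
`sample_id species setting fwd_index rev_index is_negative_control`
plus an optional `subject_id` naming the physical specimen when one
specimen was amplified under several PCR settings (used to deduplicate
the union food web).

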