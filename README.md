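# myxocol

Toolkit for contamination-aware transcriptome filtering and minicollagen
domain-architecture analysis.

It covers two workflows:

1. **Post-assembly decontamination.** Assembled transcript contigs are
   screened against BLAST tabular hit files: contigs with *any* hit to the
   host are removed first, then contigs whose identity-weighted hit coverage
   against a closely related co-infecting species exceeds a similarity
   threshold (default: strictly greater than 0.90) are removed. The
   similarity score of a contig is `Σ(per-base best HSP identity) / contig
   length`, pooled across all subjects; a plain coverage mode
   (`coverage_only`, fraction of bases covered at identity ≥ floor) is
   available behind a flag.
2. **Minicollagen characterisation.** A protein scanner locates cysteine-rich
   domains (CRDs) by inter-cysteine spacing patterns (canonical
   `C-3-C-3-C-3-C-3-CC`, noncanonical `C-3-C-9/10-C-3-C-3-CC`, and
   polyproline-interrupted variants), counts Gly-X-Y collagen triplet
   repeats, classifies linker composition (polyP / SG-rich / other), checks
   the propeptide-terminal KR dipeptide, and applies a rule table to call
   the minicollagen type (Ncol-5, Ncol-4, Ncol-1/2/3-group, or
   unclassified). Supporting modules locate introns by exact
   transcript-vs-genomic comparison, compute gene-pair intergenic distances
   and orientations on scaffolds, mine orthologs (CRD query extraction,
   E-value gating, reciprocal best hits), prepare alignment-ready sequences
   with polyproline linkers excised, and report assembly QC statistics
   (N50, GC).

Everything is testable offline: the `synth` module generates seeded,
deterministic fixtures (divergent contaminant contigs with exact truth
tables, proteins with planted domain architectures, genomic sequences with
planted introns and gene clusters).

## CLI

All subcommands write results to files; stdout/stderr carry logs only.
Exit codes: 0 success, 1 user/input error, 2 internal error.

```sh
# two-stage contamination filter
myxocol filter --assembly asm.fasta --host-hits host.tsv \
    --contam-hits contam.tsv --threshold 0.90 --mode weighted \
    --out-kept clean.fasta --report report.tsv

# assembly statistics (contig count, total length, N50, GC%)
myxocol qc --assembly asm.fasta --out stats.tsv

# minicollagen domain scan + typing
myxocol scan --proteins prot.fasta --out-gff domains.gff3 --out-table calls.tsv

# ortholog mining on parsed BLAST tables
myxocol mine --proteins prot.fasta --annotations domains.gff3 \
    --hits fwd.tsv --reciprocal-hits rev.tsv --evalue 1e-5 --out mined.tsv

# intron localisation (transcript vs genomic amplicon, exact matching)
myxocol introns --transcript tx.fasta --genomic amp.fasta --out introns.tsv

# gene-cluster geometry (IGR length + orientation)
myxocol cluster --loci loci.tsv --max-igr 100000 --out clusters.tsv

# alignment preparation (polyproline linkers excised)
myxocol prep --proteins prot.fasta --annotations domains.gff3 --out trimmed.fasta

# synthetic fixtures (deterministic under --seed)
myxocol simulate --seed 1 --outdir fixtures/
```

BLAST input is the default 12-column tabular dialect (`qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore`). Gene loci
are 5-column TSV (`scaffold start end strand name`) or GFF3 gene rows.

## Package layout

| module        | contents |
|---------------|----------|
| `seqio`       | FASTA / BLAST-tab / GFF3 readers & writers, coordinate conversions |
| `hitcov`      | per-contig hit-coverage merging, similarity scoring, two-stage filter |
| `asmqc`       | N50, GC fraction, assembly summaries |
| `mining`      | CRD query extraction, E-value gating, reciprocal best hits |
| `ncolscan`    | CRD motif search, Gly-X-Y counting, linker/KR analysis, Ncol typing |
| `intronmap`   | exact transcript-vs-genomic intron localisation |
| `genecluster` | intergenic distances and strand-orientation classes |
| `phyloprep`   | polyproline excision with reversible coordinate maps |
| `synth`       | seeded synthetic-data generators with exact truth tables |
| `cli`         | `myxocol` command-line entry point |
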