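# tegenomics

Genome-context analytics for transposable-element-rich fungal genomes.
The package implements five analyses plus a synthetic-data generator with
planted ground truth:

- **genome_stats** — assembly statistics (total length, N50, overall and
  coding/noncoding GC), gene-model statistics (density, percent coding,
  exon/intron profiles), the complete-CDS filter (start codon, stop codon,
  no internal stop), and per-gene intergenic distances.
- **te_context** — detection of TE-surrounded genes (a repeat longer than
  400 bp intersecting a 1000 bp window on *both* flanks), the association
  between TE context and transcriptional silencing (with a Fisher exact
  test), and paralog/ortholog rescue evidence.
- **rip** — RIP-style C→T hypermutation statistics over repeat-family
  alignments: per-copy transition/transversion counts, dinucleotide-context
  (CpA/CpC/CpG/CpT) binning with reverse-strand G→A mapping, and the
  family-level call (pooled ti/tv > 2 and more than one third of copies
  showing a dominant context).
- **expression** — stage-wise FPKM classification: expressed (> 1 FPKM)
  and strict-zero calls, pseudocount log2 fold changes, the seven-way
  expression-pattern labels (three single-stage enriched, three two-stage
  co-overexpressed, not-significant), transition up/down sets, the
  constitutive top-k set, and Fisher exact category enrichment computed by
  exact hypergeometric summation.
- **voting** — multi-tool integration: 3-of-4 secretome voting with the
  TM/ER/GPI exclusion cascade, small-secreted-protein (< 300 aa) and
  cysteine-rich (> 3 % Cys) classification, CAZyme agreement voting,
  three-way gene-support evidence, and Pfam-list tagging/filtering.
- **simulate** — deterministic synthetic genomes, gene/repeat annotations,
  RIP-mutated repeat families, three-stage FPKM tables and vote tables,
  all with machine-checkable planted truth (`truth.json`).

Coordinates are 0-based half-open internally; GFF3 and RepeatMasker `.out`
conventions are converted at the I/O boundary. Supported formats: FASTA,
GFF3 (gene/mRNA/exon/CDS), RepeatMasker `.out`, a 6-column BED-like repeat
TSV, and typed TSV tables.

## Command line

A single executable with subcommands; every subcommand takes `--out-dir`
and an optional `--config` YAML file of threshold overrides, and embeds
its configuration in the JSON report it writes.

```sh
# generate a synthetic dataset with planted truth
tegenomics simulate --seed 1 --out-dir demo

# assembly + gene statistics
tegenomics stats --fasta demo/genome.fa --gff3 demo/genes.gff3 --out-dir demo/stats

# TE-surrounded genes and silencing association
tegenomics te-context --gff3 demo/genes.gff3 --repeats demo/repeats.tsv \
    --fpkm demo/fpkm.tsv --fasta demo/genome.fa --out-dir demo/te

# RIP statistics over per-family alignments
tegenomics rip --families-dir demo/families --out-dir demo/rip

# expression patterns, transitions, constitutive set
tegenomics expression --fpkm demo/fpkm.tsv --out-dir demo/expr

# secretome / SSP / CAZyme voting
tegenomics vote --secretion demo/votes/secretion.tsv \
    --cazyme demo/votes/cazyme.tsv --out-dir demo/vote
```

RepeatMasker `.out` input is selected with `--repeat-format rmout`.

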