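# sirnakit

Small-RNA duplex discovery and heat-stress differential-expression analysis,
end to end: raw small-RNA FASTQ libraries → cleaned unique tags →
exact-match genome mapping with structural-RNA subtraction → siRNA duplex
calling via the 2-nt 3′-overhang (Dicer signature) geometry → TPM-based
differential expression over a 0/1/6/12-hour time course → fuzzy c-means
temporal clustering → dual-scheme consensus target prediction →
hypergeometric GO enrichment → 2^−ΔΔCT qPCR cross-validation.

A synthetic-data module generates a complete toy experiment (genome,
annotations, planted duplex loci with temporal fold changes, four
adapter-ligated FASTQ libraries, transcriptome with planted target sites,
GO map, qPCR Ct table) with a truth table, so every stage is testable
without any downloads.

## CLI

All stages are subcommands of the `sirnakit` console script:

```bash
# generate a synthetic experiment with planted ground truth
sirnakit simulate --seed 1 --outdir sim/

# full preprocess -> map -> call -> DE pipeline
sirnakit run --genome sim/genome.fa --annotation sim/annotation.gff3 \
    --fastq-0h sim/lib_0h.fastq --fastq-1h sim/lib_1h.fastq \
    --fastq-6h sim/lib_6h.fastq --fastq-12h sim/lib_12h.fastq \
    --outdir out/

# individual stages
sirnakit preprocess --fastq-0h ... --outdir pre/        # adapter/quality/length + collapse
sirnakit map --genome ... --tags pre/tags.tsv ...       # exact match + subtraction
sirnakit call --genome ... --tags pre/tags.tsv ...      # duplex calling
sirnakit de --catalogue out/sirna_catalogue.tsv --cleanup-stats pre/cleanup_stats.tsv ...
sirnakit cluster --de-table out/de_table.tsv --c 4 --seed 0 --outdir clusters/
sirnakit targets --catalogue out/sirna_catalogue.tsv --transcripts sim/transcripts.fa --out hits.tsv
sirnakit enrich --targets hits.tsv --go-map sim/go_map.tsv --out enrichment.tsv
sirnakit qpcr --ct-table sim/qpcr_ct.csv --de-table out/de_table.tsv --outdir qpcr/
```

`sirnakit simulate` accepts `--config config.yaml` with any
`SimulationConfig` field (depths, fractions, fold sizes, adapter, seed...).

## Key conventions

- Coordinates are 0-based half-open internally; GFF3 converts at the
  boundary. Duplex geometry: `plus.start − minus.start == 2` and
  `plus.end − minus.end == 2`; a relaxed 1–3-nt overhang mode exists behind
  `--relaxed-geometry`.
- Abundance criterion: strictly more than 5 raw reads per library
  (`--per-sample-mode any` relaxes to at least one library).
- DE: TPM normalization against total mapped cleaned reads, records with
  TPM < 30 in every library excluded, exact conditional binomial test
  (Fisher's exact as `--test fisher`), status `up`/`down` at
  |log2 ratio| ≥ 1 and p < 0.05.
- Target consensus: a site must pass both scoring schemes (position-weighted
  penalties with G:U wobble = 0.5, core/seed weighting) at the same site.

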