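# petalseq

A tested, reusable reimplementation of a de novo transcriptome comparison
pipeline for two flower-color morphs sampled in two populations:

1. **synthdata** — synthetic reference gene sets, a diverged two-haplotype
   focal transcriptome with ground-truth expression and fold changes,
   3'-biased single-end reads (FASTQ), multi-kmer contig sets emulating a de
   Bruijn assembler, GO annotation tables, and qPCR CT tables.  Everything a
   downstream stage needs is generated offline from one seed.
2. **homology** — contig-to-gene assignment: an ungapped seed-and-extend
   aligner (word size 11, +1/−2 scoring) with Karlin–Altschul E-values
   (λ solved from base composition, K from the standard lattice series,
   matching the published blastn constants), thresholded at E < 10⁻¹⁰ and
   filtered by reciprocal best hits.
3. **consensus** — reference-anchored per-gene alignment of contigs from both
   morphs, IUPAC-ambiguity consensus with lowercase `n` padding, per-gene kmer
   selection under a 1.9% ambiguity ceiling, QC triage (re-anchoring,
   conserved-CDS/divergent-UTR paralog detection, divergent-contig removal),
   and CDS-coverage reporting.
4. **mapper** — hash-seeded read mapping (hash length 14, ≤ 2 mismatches,
   IUPAC-aware matching); only uniquely placed reads are counted, with full
   read-fate accounting (unique / multi / mismatch-filtered / unseeded).
5. **expression** — RPKM on non-`n` consensus length, a ≥ 10-reads-per-sample
   filter, relative difference RD = (P−W)/max(P,W) per population,
   the cross-population consistency statistic, ±0.5 / ±0.25 classification,
   and per-position fold-change profiles.
6. **enrichment** — top-2% study sets per direction, null-set construction,
   exact hypergeometric enrichment/depletion with Benjamini–Hochberg
   adjustment at q < 0.01 and q < 0.05 tiers.
7. **validation** — qRT-PCR arithmetic (linearized ΔCT, ΔΔCT
   standardization, log-log OLS with named outlier exclusion) and
   genome-size conversion (1 pg diploid DNA = 978 Mbp).
8. **pipeline / cli** — one-config orchestration with a manifest and
   byte-identical reruns for a fixed seed.

## CLI

```bash
petalseq all --config config.yaml --outdir out/ --seed 7
petalseq simulate --outdir out/ --seed 7      # stop after a given stage
petalseq check-config --config config.yaml
```

Config keys mirror `petalseq.pipeline.PipelineConfig` one-to-one (thresholds,
kmer list, read counts, planted DE genes, seed).  Stage subcommands rerun the
deterministic prefix of the pipeline ending at that stage — all randomness
flows from the single config seed, so any prefix is reproducible.  Outputs
are plain text: FASTA/FASTQ, TSV tables (hits, consensus stats, mapping
summary, expression, differential, enrichment), `manifest.json`.

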