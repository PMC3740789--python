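# methylannot

Expanded annotation toolkit for Infinium-style DNA-methylation array probes.
Given a (soft-masked) genome FASTA, a GenomeStudio-style probe manifest, a
dbSNP-style SNP table and a refGene-style gene-model table, it produces a
merged per-probe annotation covering:

- **probe coordinates** — target-CpG, probe-without-CpG and entire-probe
  intervals derived from MAPINFO, with sequence round-trip validation
  against the genome;
- **polymorphic targets** — SNPs at the C or G of the interrogated CpG
  (1-bp, weight-1 SNPs only), plus <10 bp / >10 bp proximity classes;
- **binding specificity** — an in-silico bisulfite screen against four
  converted genome variants (unmethylated/methylated × forward/reverse
  complement) with exact-seed candidate search, 3'-anchored ungapped
  scoring, the ≥90% identity / ≥40-of-50 matches / no-gaps / aligned-50th-
  base acceptance filter, cross-hybridization summaries and repetitive-bp
  counts from soft masking;
- **CpG landscape** — genome scans for high-density (HC: CG>55%, Obs/Exp
  CpG>0.75, >500 bp) and intermediate-density (IC: CG>50%, Obs/Exp>0.48,
  >200 bp) islands, merged into HC / ICshore / IC / LC probe classes, plus
  UCSC-style island / shore / shelf / sea classes;
- **gene features** — nine-way classification (first exon / exon / intron ×
  5'UTR / body / 3'UTR) across all overlapping transcripts, and closest-TSS
  annotation;
- **methylation statistics** — β/M transforms, within-group SD screening,
  methylation-level categories, two-sample KS comparisons, z-score
  differential methylation with Bonferroni control, signed percentage
  relative enrichment, and an FDR + Δβ sex-difference screen.

A `synthetic fixtures` module generates all inputs deterministically with
planted ground truth, so everything is testable offline.

## CLI

```sh
# generate a self-contained fixture (genome, manifest, SNPs, genes, truth)
methylannot fixtures make --preset default --seed 0 --out fixtures/

# end-to-end annotation
methylannot annotate --manifest fixtures/manifest.tsv \
    --genome fixtures/genome.fa --snp-table fixtures/snps.tsv \
    --gene-table fixtures/genes.tsv --out-dir out/

# individual stages
methylannot islands scan --genome fixtures/genome.fa --mode hil --out islands.bed
methylannot probes classify-cpg --manifest fixtures/manifest.tsv \
    --islands islands.bed --out classes.tsv
methylannot specificity run --manifest fixtures/manifest.tsv \
    --genome fixtures/genome.fa --out specificity.tsv
methylannot snps annotate --manifest fixtures/manifest.tsv \
    --snp-table fixtures/snps.tsv --out snps_out.tsv
methylannot genes annotate --manifest fixtures/manifest.tsv \
    --gene-table fixtures/genes.tsv --out genes_out.tsv

# beta-matrix statistics (probes x samples TSV + sample metadata sidecar)
methylannot fixtures make --preset snp-demo --seed 1 --out demo/
methylannot stats sd --beta demo/beta.tsv --samples demo/samples.tsv --out sd.tsv
```

Exit codes: 0 success, 2 input error, 3 partial annotation (sections skipped
because optional inputs were absent).

## Layout

```
src/methylannot/
  core.py         probe records, interval arithmetic, sequence validation
  io.py           FASTA / manifest / SNP / gene-table / BED / annotation I/O
  islands.py      CpG island scanning and HIL / UCSC classification
  specificity.py  bisulfite variants, seeded search, hit filter, summaries
  snps.py         target-CpG SNP annotation and proximity classes
  genes.py        nine-way gene features and closest TSS
  stats.py        beta-matrix statistics
  fixtures.py     deterministic synthetic-data generators with planted truth
  pipeline.py     merged end-to-end annotation
  cli.py          click front end
tests/            unit, property and acceptance tests (+ brute-force oracles)
scripts/acceptance.py
```
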