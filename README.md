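# capscreen

Post-alignment analysis for **targeted-capture resequencing of candidate
linkage regions in families** — the setting of hereditary disease studies in
which a handful of affected relatives (and a pooled control of healthy
unrelated individuals) are sequenced over the exons of a linkage candidate
region, and the goal is the short list of rare heterozygous variants that
segregate in each family.

The package covers everything between the aligner and the Sanger bench:

* **Depth & coverage accounting** — per-base pileups over the capture
  targets, coverage (% of target bases with depth > 0), mean/median depth
  over covered bases, and the fold enrichment of the capture
  (on-target % of aligned reads ÷ the target's % of the genome).
* **Coverage-homogeneity QC** — a CGH-style windowed index. The targets are
  tiled with 15-base windows and each window is scored

  ```
  Is = log2( ((m_s + pc) / M_s) / ((m_c + pc) / M_c) )
  ```

  where `m_s`, `m_c` are the window median depths of sample and control
  pool, `M_s`, `M_c` their global medians, and `pc` a pseudocount (0.5).
  Windows outside `mean ± (SD + 0.5)` are flagged as putatively altered
  capture regions.
* **Allele-balance variant calling** — a heterozygote-oriented SNP/indel
  caller scoring every call with two statistics built on one formula,
  `score = 100 · X_V / X_R`: the **Depth Score (DS)** uses the variant- and
  reference-allele read depths, the **Quality Score (QS)** the mean
  base-call qualities. Scores near 100 mean both alleles are equally
  represented — the signature of a true heterozygote. The caller's primary
  filter removes calls with global depth < 10 or DS < 50.
* **The family filtering cascade** — restriction to the family's linkage
  chromosome, removal of homozygous calls, subtraction of variants seen in
  the pooled control (control DS ≥ 14 counts as evidence), intersection
  across affected members, removal of already-described variants (local
  VCF), consequence annotation against local GFF3 gene models (codon
  translation, essential splice sites, UTRs, non-coding genes), removal of
  purely intronic variants, and a deterministic homology check (the 61-base
  flanking context must be unique genome-wide up to 2 mismatches, and most
  supporting reads must be single-hit). A separate truncating-variant scan
  reports stop-gains and splice-site hits per individual regardless of
  family sharing.
* **Evaluation** — DS-threshold sweeps with false-positive/false-negative
  rates against confirmation labels, and confirmation statistics (rate,
  per-group DS summaries).
* **Synthetic experiments** — a seeded generator
  (`capscreen.synthetic_data`) that emulates the whole study design:
  barcoded multiplexed samples, families sharing planted heterozygous exonic
  variants, decoy variants for every filter, capture-style uneven depth,
  and duplicated (homologous) loci — with a machine-readable truth set.

## Worked example

Generate a synthetic experiment (two 2-member families, four pooled
controls, 33× mean depth, sequencing errors, capture bias and homologous
decoys), then run the pipeline on it:

```
$ capscreen simulate --seed 4 --out sim --fastq
wrote 17 files to sim

$ capscreen depth --sam sim/S1.sam --bed sim/targets.bed --ref sim/reference.fasta --out rpt
coverage 100.0%  mean depth 33.4  median 32.0

$ capscreen covqc --sample-sam sim/S1.sam --control-sam sim/control_pool.sam \
    --bed sim/targets.bed --ref sim/reference.fasta --out rpt
Is mean -0.02 sd 0.6 thresholds [-1.12, 1.08]; 5 windows flagged (2 at region edges)

$ capscreen call --sam sim/S1.sam --bed sim/targets.bed --ref sim/reference.fasta --out rpt/S1.vcf
12 raw calls, 8 after primary filter -> rpt/S1.vcf

$ capscreen cascade --manifest sim/manifest.tsv --sam-dir sim --bed sim/targets.bed \
    --gff sim/genes.gff3 --known sim/known.vcf --ref sim/reference.fasta --out rpt
2 candidate variants across 2 families -> rpt/candidates.tsv

$ cat rpt/candidates.tsv
family  chrom  pos   ref  alt  qs      ds      consequence
F1      chr1   1031  C    G    101/98  78/123  NON_SYNONYMOUS_CODING
F2      chr2   1034  T    C    98/102  96/100  NON_SYNONYMOUS_CODING
```

Reading the output: sample S1's capture behaved like the control pool (all
window indexes inside the thresholds; the few flagged windows sit at region
edges, where low coverage makes the index noisy). The cascade reduced each
family's raw calls to exactly one candidate — in both cases the variant the
generator actually planted as the shared, heterozygous, exonic, undescribed
allele (`sim/truth.json`); every decoy (private, control-carried, known,
intronic, homologous, off-chromosome) was removed by the stage designed for
it. The `qs`/`ds` columns give per-member scores: values near 100 indicate
balanced alleles in both carriers.

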