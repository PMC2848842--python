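# Methods

## Setting and model

The pipeline analyses single-end short-read data captured over the exons of
linkage candidate regions. Families contribute ≥1 affected members each with
a designated candidate chromosome (from a prior linkage analysis); several
healthy unrelated individuals are pooled into one control pseudo-sample.
Alignments are consumed as SAM; the expected alignment regime is ≤2
mismatches, at most one gap of ≤12 bases per read, and up to 5 equally good
placements per read, all of which are reported (one SAM record per
placement, the placement count in the `NH` tag). Retaining multi-hit reads
is deliberate: discarding them would silently blind the screen in
near-duplicated sequence; ambiguity is instead resolved late, by the
homology check.

All internal coordinates are 1-based inclusive; BED is converted at the
boundary.

## Depth, coverage, enrichment

Depth at a base is the number of kept placements covering it (multi-hit
placements each count fully — no fractional weights). Coverage is the
percentage of target bases with depth > 0; mean/median depth are computed
over covered bases only, though the per-base vector (zeros included) is also
exposed. Fold enrichment is `pct_on_target / pct_target_of_genome`, a
scale-invariant ratio of two percentages. Percentages are reported rounded
half-up to 2 decimals, matching how such tables are printed.

## Coverage-homogeneity index

Targets are tiled with non-overlapping 15-base windows (a trailing shorter
window is kept and flagged partial). For each window,

    Is = log2( ((m_s + pc) / M_s) / ((m_c + pc) / M_c) )

with window medians `m_s`, `m_c`, global medians `M_s`, `M_c`, and
pseudocount `pc = 0.5`. Flagging thresholds are `mean ± (SD + 0.5)` over the
window set, with the population SD (ddof = 0). Three details here are
reconstructions, because the original displayed formulas survive only as
prose: the log base (2, the CGH convention; configurable), the pseudocount
(the original treatment of zero-coverage windows is unstated; 0.5 keeps the
index finite), and strict inequalities at the thresholds (boundaries
unstated). The `mean ± (SD + 0.5)` form reproduces all 21 printed
threshold pairs of the original study within ±0.01, which is the accuracy
limit imposed by the 2-decimal printed inputs; the sample-vs-population SD
distinction is likewise unresolvable at that precision. Flagged windows
carry a region-edge annotation because target flanks are naturally
low-coverage and dominate the flags by chance.

## DS/QS scores and calling

At each pileup column the best-supported non-reference allele (by depth,
then mean quality, then lexicographic order — a total order, so output is
deterministic) becomes the alt; a call requires ≥2 supporting reads. Two
scores share one formula, `score = 100 · X_V / X_R`: allele read depths for
DS, mean base qualities for QS. A site with no reference-allele evidence
returns a large homozygous sentinel and is classified `hom` (the expected
causal variants are rare heterozygotes, so homozygous calls are dropped by
the cascade). The exact original score formula is another lost figure; the
ratio form is the default here because confirmed heterozygotes in the
original screen printed DS values up to 185 — a variant-read fraction of
~0.65 under the ratio form, but ~0.93 under the bounded alternative
`200 · X_V/(X_V + X_R)`, which would contradict a heterozygote-only screen.
The bounded form remains available by configuration. The primary filter
keeps a call only if global depth ≥ 10 **and** DS ≥ 50 (a DS of exactly 50
survives); the global-depth cutoff of the original pipeline is also lost —
10 is this package's default, consistent with confirmed variants having had
depth ≥ 19.

Indels are aggregated read-wise: reads sharing (chromosome, event position,
kind, length, inserted sequence) support one VCF-style call anchored at the
base before the event; gap-free reads spanning the locus supply `X_R`, and
the same DS/QS machinery applies.

## Filter cascade

Stage order: primary filter → candidate-chromosome restriction → homozygote
removal → control subtraction → family intersection → known-variant split →
consequence annotation → intronic drop → homology check. Variant identity is
the full `(chrom, pos, ref, alt)` key throughout — the conservative,
allele-aware reading for control subtraction and the known-variant lookup
(the original's matching granularity is unstated). Control calls count as
subtraction evidence only at DS ≥ 14; one heterozygous carrier among four
pooled controls sits near DS ≈ 14 (0.125/0.875), which is why that
particular threshold separates real pool variation from noise.

Consequences are computed per overlapping transcript from local GFF3 gene
models: coding SNPs by strand-aware codon translation (standard code) into
SYNONYMOUS / NON_SYNONYMOUS_CODING / STOP_GAINED with an `aa_change`;
the two intronic bases flanking each exon are ESSENTIAL_SPLICE_SITE;
exonic-but-not-CDS positions are 5'/3' UTR; exons of CDS-less transcripts
are NON_CODING_GENE. Coding indels are reported as protein-altering without
a codon change. The intronic drop removes INTRONIC records and any variant
left with none; UTR and non-coding-gene records are retained, as such
variants were reported as candidates in the original screen. A variant
overlapping no transcript is intergenic and leaves the cascade at the
annotation stage. Stage counts are recorded in a trace: per-individual
counts up to control subtraction, per-family counts after; the consequence
stage counts records, which can exceed the variant count (one variant, many
transcripts) — the only non-contracting stage.

The homology check replaces a manual BLAT triage with a deterministic scan:
the reference context 30 bases either side of the variant (61-mer; shortened
and logged at contig edges) is searched genome-wide on both strands allowing
≤2 mismatches — matching the alignment regime — and >1 occurrence flags the
variant; independently, >50% multi-hit supporting reads flag it.

The truncating scan re-annotates each individual's post-control calls and
reports stop-gains and essential-splice-site hits regardless of family
sharing, flagging entries with DS < 50 as likely false positives; this
guards against a real truncating mutation disappearing in the intersection
because it was missed in one relative.

## Threshold sweep and confirmation statistics

The sweep reruns the cascade over a grid of (sample DS, control DS)
thresholds. Per cell: candidates before/after homology, confirmed count,
`FPR = 100·(after − confirmed)/after` (0 when empty), and
`FNR = 100·(max_confirmed − confirmed)/max_confirmed`, where
`max_confirmed` is the confirmed count at the most permissive grid point —
the definition that reproduces every printed FNR cell (25/50/75 against a
maximum of 4). Rates are printed as half-up integers; the confirmation rate
as a 2-decimal proportion. Mean group DS pools every per-member DS value in
the group.

## Synthetic experiments

The generator emulates the study design end to end: 2 two-member families
with candidate chromosomes, 4 controls pooled into one file, 5-base sample
barcodes (the four published codes first, deterministic extensions beyond),
36-base single-end reads, 33× default mean depth, per-15-base-window
negative-binomial depth scaling (gamma-mixed Poisson, dispersion 0.3 —
capture bias is not quantified anywhere, so the dispersion is a free
parameter chosen to give visibly uneven but fully covered targets), uniform
base-call errors (0.002), and heterozygous allele balance 0.5 applied
per covering read. Each target region carries a two-exon gene with UTRs and
a phase-0 CDS; a configurable fraction of regions is duplicated (0–2
mismatches) into the chromosome tail as homology decoys, and reads from
duplicated regions are emitted as two placements with `NH=2`. Around each
family's intended candidate (shared, heterozygous, exonic, undescribed) the
generator plants one decoy per filter: member-private, control-carried,
database-known, intronic, off-chromosome, in-duplicated-block, plus a
private stop-gain (for the truncating scan) and a private intronic deletion
(so the indel branch ends empty, as in the original screen). Control-carried
decoys are planted in 2 of the 4 controls: a single pool carrier lands
exactly at the DS ≈ 14 control boundary, where the logical truth oracle
would be undecidable, while two carriers (DS ≈ 33) model the common
population variant the subtraction is meant to remove.

What the generator does **not** model: position-dependent error profiles,
PCR duplicates, paired-end information, strandedness of reads (all reads are
emitted forward), indel sequencing errors, and real population allele
frequencies. Passing tests therefore demonstrate the correctness of the
pipeline's logic and arithmetic under the stated sampling model, not
robustness to every artefact of real capture data.

`expected_candidates` applies the cascade's logical definition directly to
the truth set and is the oracle for end-to-end tests.

## Numerical and testing choices

* Printed-style rounding is half-up (`Decimal`), not banker's.
* Determinism: one `numpy` generator seeded from the config drives all
  randomness in a fixed order; identical configs give byte-identical files.
* Exact-equality oracle tests run error-free at 120× sample depth: the
  DS ≥ 50 filter misses a balanced heterozygote with probability
  P(Bin(d, ½) < d/3) — about 2% at 30×, ~9·10⁻⁵ at 120× — so at high depth
  exact candidate-set equality over 20 seeded replicates is a fair
  expectation, while at 30× it is not. For the same reason, caller recall at
  30× is asserted at ≥99% for *detection* (≥2 supporting reads), and the
  DS-filtered pass rate is tested against its binomial expectation rather
  than a flat bound.
* Test problem sizes: 2 chromosomes × 20 kb, 4 × 300-base regions,
  families of 2, depths 30–120×; the acceptance script's self-check runs one
  such replicate. These sizes exercise every code path while keeping the
  suite fast.

## Known limitations

* Three quantities of the original pipeline are reconstructions of lost
  figures (score formula, global-depth cutoff, Is threshold margin); each
  reproduces all printed values it touches, but alternatives cannot be
  excluded. All are configurable.
* The homology scan is exact brute force and scales as genome × candidates;
  it is intended for candidate-sized inputs, not genome-wide call sets.
* Consequence annotation handles one transcript model per record and does
  not attempt frameshift/extension annotation for coding indels.
* Single-end logic only; large rearrangements are out of scope.
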