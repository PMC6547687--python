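# Methods

`staract` implements the analysis of an allele-resolved massively parallel
reporter assay (MPRA) of the STARR-seq type: candidate regulatory windows
carrying either allele of a SNP sit inside the reporter transcript, so each
window's RNA abundance, normalized by its DNA abundance in the plasmid
pool, reports its own regulatory activity. This note records the models,
conventions, and numerical choices behind each stage.

## Library design

For each biallelic SNP the design module extracts the 196-nt genomic
window centered on the variant from the plus strand of the supplied
reference, edits the variant base to produce both allelic states, and
flanks each insert with the two cloning adaptors
(`TCTAGAGCATGCACCGG` / `GCCGGTCAGAATGATGG`), yielding 230-nt oligos.
"Centered" is ambiguous for an even window length; we fix the variant at
1-based offset 98 within the insert (97 nt upstream, 98 nt downstream), so
the insert spans `[pos-98, pos+98)` in 0-based half-open coordinates.
That single declared convention keeps read assignment, the emitted BED
intervals, and downstream overlap arithmetic mutually consistent. Windows
that fall off the chromosome, and records whose reference base matches
neither allele, are hard errors: silent clipping would desynchronize the
insert set from the reference FASTA used for read assignment.

## Generative model of the screen (simulator)

The synthetic-data generator reproduces the statistical structure the
analysis relies on, not sequencing realism:

* **Barcoding.** Each allele receives a truncated-Poisson number of
  degenerate 5-mers (mean `barcodes_per_allele`, at least 1), drawn
  uniformly over the 4^5 barcode space with collisions allowed. The
  barcode set is created once — as in the actual chemistry, where barcodes
  are added during PCR before cloning — and shared by all replicates.
* **Bottlenecking.** Each barcode independently survives library
  construction with probability `1 - dropout_prob`; alleles can lose all
  barcodes and drop out of the screen entirely.
* **Abundance and readout.** Per-barcode plasmid abundance is
  LogNormal(0, `dna_abundance_logsd`). DNA reads per replicate are Poisson
  draws from the normalized abundances at `dna_depth`; RNA reads are
  Poisson draws from abundances multiplied by `2**(activity + eps)`, with
  `eps ~ Normal(0, rna_noise_sd)` per barcode and replicate. This
  log-normal–Poisson mixture is the minimal model that reproduces MPRA
  overdispersion.
* **Truth.** Baseline activities are Normal(0, `activity_sd`); a fraction
  `frac_differential` of SNPs shifts its minor allele by `effect_log2`.

Defaults (3 replicates, 5 barcodes/allele, 20% dropout, `activity_sd` 1.0,
`rna_noise_sd` 0.5, depths 1e6, `effect_log2` 1.32 — i.e. a 2.5-fold
shift) were chosen so that a default screen lands in the regime the assay
operates in: roughly 12 scored measurements per allele and
between-replicate Spearman correlations near 0.9. The simulator does not
model PCR chimeras, quality-score structure, or jackpotting beyond the
log-normal abundance; passing recovery tests therefore demonstrates
correctness of the statistical pipeline under this generative model, not
robustness to every artifact of real libraries. The true bottleneck
process of a real screen is unknown; `dropout_prob` is a deliberately
crude stand-in, and allele-recovery rates should be read accordingly.

Simulated reads have the fixed layout `insert(196) + adaptor(17) +
barcode(5)` in a single synthetic read with constant base quality;
substitution errors are applied per base at `read_error_rate`.
Instrument-specific details (paired ends, indexing) are out of scope.

## Read counting

Reads are assigned by exact match of their first 196 nt against the
insert reference — the deterministic equivalent of aligning and keeping
only error-free molecules. Because allelic insert pairs differ at exactly
one base, assignment is unambiguous whenever it succeeds. The 17-nt
adaptor preceding the barcode must also match exactly (any adaptor error
marks an error-prone molecule), and barcodes containing non-ACGT bases
are rejected. Rejected reads are tallied per reason, and the table
satisfies read conservation: assigned + rejected = input, per pool.
A consequence of the exact-match rule worth noting: a substitution error
at the SNP base itself converts a read into a perfect copy of the other
allele and is counted there. At a 1% per-base error rate this inflates
apparent retention by about 0.05 percentage points and mis-assigns about
0.3% of retained reads — negligible at the effect sizes tested, but a
reason the simulator's default error rate is kept at 0.1%.

## Activity scores

One measurement is one (variant, allele, barcode, replicate) class with at
least 10 DNA reads and at least 1 RNA read; its score is
`log2((rna/rna_total) / (dna/dna_total))`. Pool totals are totals of
*assigned* reads per replicate and pool, so the normalization is internal
to the quantified library; raw FASTQ read counts (which include rejected
molecules) play no role. No pseudocounts are used — the RNA >= 1 filter
already excludes zeros. Scores are exactly invariant to rescaling either
pool's depth. Alleles need at least three measurements, pooled across
replicates, to receive a mean activity; under-sampled alleles are
reported in a dropped-allele table rather than silently discarded.
Replicate concordance is computed on per-replicate mean allele scores
over alleles scored in both members of a pair.

## Differential testing

Minor-vs-major measurement scores are compared per SNP with a two-sided
Mann-Whitney U test (either allele may be the more active). The exact
null distribution is used when both groups have at most 8 observations
and no ties — giving deterministic small-sample p-values for fixtures —
otherwise the normal approximation with tie and continuity corrections.
Measurements are pooled across replicates for the test, consistent with
the scoring filters. Benjamini-Hochberg step-up across all tested SNPs
controls the FDR at 0.10; the family size is the number of SNPs with both
alleles scored. The effect size is `2**(mean_minor - mean_major)`, the
fold change of the minor allele on the linear scale.

## Quintile enrichment

Major-allele regions are ranked by mean score into quintiles (5 =
highest), ties broken by SNP id. Sizes follow a ceil/floor partition with
the remainder assigned to the highest quintiles first: 1,254 regions
split 251/251/251/251/250 from the top down. Overlap with a peak set
requires at least 1 bp intersection in half-open coordinates (computed
via pyranges); an "any dataset" union flag is also derived. Enrichment
contrasts (top quintile vs. rest; top vs. bottom quintile) use the
Pearson chi-square on the 2x2 table *without* Yates continuity
correction — the variant that reproduces the screen's printed p-values
from its printed counts — with Bonferroni correction across however many
datasets are supplied to the invocation. Tables with any expected cell
below 1 are computed but flagged unreliable.

## Allelic expression imbalance

Per technical replicate, the imbalance is
`(rna_minor/rna_major) / (dna_minor/dna_major)` — the DNA ratio calibrates
amplification bias — tested by a two-sided Fisher exact test on the
allele-by-pool table. Reads are classified only if they exactly equal one
expected amplicon over its length; length changes (indels) and any
mismatch are discarded. For the patient cohort, each patient's
minor-allele fraction is averaged over technical replicates within DNA
and within RNA, and the two per-patient sets are compared with a
two-sided Mann-Whitney U test using the exact null for cohorts of nine or
fewer patients (deterministic even under ties); the summary effect is the
median over patients of the per-patient odds-ratio fold. Patients missing
an entire pool are excluded with a warning rather than imputed.

## Enhancer-activity model

Features flagged as right-skewed signal (explicitly, or auto-flagged at
sample skewness > 1) are log(x+1)-transformed; all features are then
z-scored so lasso coefficients are comparable; constant features are
dropped. The L1 penalty is chosen by 10-fold cross-validation minimizing
mean squared error over a log-spaced grid (the 1-SE rule is available as
an option); the final model is refit on all rows at the chosen penalty,
and reporting takes the 30 coefficients of greatest magnitude with signs
retained. Out-of-fold predictions — each row predicted by a model trained
without it — are scored against observed activity by Spearman rank
correlation. By default the penalty is re-tuned inside each training fold
(nested CV), so penalty selection cannot leak held-out information into
the evaluation; a non-nested mode re-uses the single full-data penalty
per fold and is noticeably cheaper on repeated simulation studies, where
support-recovery conclusions are unchanged. Fold assignment is seeded
and recorded row-by-row.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (numpy Generator);
identical seeds give bit-identical tables, FASTQ files, and manifests.
Simulation studies in the test suite and acceptance script use 20
replicate screens of 100-200 SNPs, 500x100 feature matrices, and ~60k
simulated reads for the counting checks — sizes at which every Monte-Carlo
margin used in an assertion is comfortably resolved while the whole suite
runs in a few minutes on one CPU. The demo pipeline defaults to 200 SNPs
at 1e5 reads per pool per replicate.

## Known limitations

* Exact-match counting discards molecules a gapped aligner might rescue;
  with 196-nt inserts at realistic error rates most molecules carry at
  least one error, so absolute retention is low by construction and all
  inference rests on the retained error-free subset.
* The simulator's noise model is stationary across barcodes and
  replicates; batch effects, transfection-efficiency differences between
  replicates, and sequence-dependent PCR bias are not modelled.
* The cohort AEI arm assumes technical replicates are exchangeable within
  patient; it does not model replicate-level overdispersion in the test
  itself (only in the simulator).
* The enrichment module treats peaks as binary intervals; signal strength
  and region-length or GC matching of backgrounds are out of scope.
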