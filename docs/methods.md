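# Methods

## Model

At a biallelic SNP in a diploid sample called heterozygous (GT = 0/1), the
number of RNA-seq reads supporting the alternate allele is modelled as
X ~ Binomial(n, θ) with n = ref + alt reads taken verbatim from the VCF
`AD` field and null θ = 0.5. The per-sample test is the exact two-sided
binomial test; because the null is symmetric this is
p = min(1, 2·P(X ≥ max(ref, alt))), which equals 1 at perfect balance. No
normal approximation is used at any depth; tails are computed through the
regularised incomplete beta function and agree with integer enumeration of
the Binomial(n, ½) pmf to 10⁻¹² for all n ≤ 60 (checked in the test suite).

Two inferential layers sit on top:

* **ASE variants** — Fisher's method per variant,
  X = −2 Σ ln pᵢ ~ χ²(2k), then Benjamini–Hochberg step-up across all m
  informative variants; declared at adjusted p ≤ α. Fisher's method asks
  whether the *collection* of samples deviates from 50:50; it does not
  require the deviation to share a direction across samples.
* **ASE samples (mdFDR)** — a two-stage screen-then-test procedure. The
  Stage-1 screening p-value per variant is the Šidák-corrected minimum
  1 − (1 − min pᵢ)^k (exact under independence); BH across variants at α
  selects R of m. Stage 2 tests each sample of a selected variant at
  α·R/(m·k): a within-variant Bonferroni share scaled by the selection
  fraction, the combination that keeps the expected proportion of variants
  carrying any false or wrongly-directed per-sample claim at or below α.
  The direction attached to a significant sample is the observed count
  ordering (a significant sample can never be a tie, since equal counts
  give p = 1). The screening statistic is pluggable
  (`screening="fisher"` uses the Fisher combined p instead): the Šidák
  minimum is powerful when one sample deviates strongly, the Fisher screen
  when many deviate weakly. The two models legitimately disagree on
  variant counts; the only set relation guaranteed is that both call
  subsets of the informative set.

p-values of exactly 0 (possible at extreme counts by floating-point
underflow) are clamped to the smallest positive normal double before the
log transform, with a warning. BH sorting is stable, so ties resolve by
input order and results are deterministic.

## Filter cascade

Order is fixed so the accounting is reproducible; each removed site gets
exactly one reason and the counts partition the input
(Σ removals + informative = total, an exact integer identity):

1. *(optional)* INFO prefilter, first violated criterion in order
   FS > 30 (strand bias), QD < 2 (quality by depth), DP < 100 (site depth);
   absent keys pass. Off by default — call sets usually arrive with these
   hard filters already applied upstream.
2. caller verdict: FILTER ∉ {PASS, "."} → `gatk_fail`;
3. indel (any allele longer than 1 bp), multiallelic (> 1 ALT), low QUAL
   (site QUAL < 20 or missing — the QUAL column, not per-sample GQ, since
   site-level filtering precedes sample-level);
4. indel proximity: a SNP within 75 bp (inclusive; one read length) of any
   indel on the same chromosome, *including* indels that themselves failed
   other filters — their sequence context is still suspect;
5. per-sample testability: called 0/1 heterozygote, ref + alt ≥ 20 reads,
   minor fraction ≥ 1% (strict-less fails; the 1% rule is applied as a
   fraction of the sample's total AD);
6. sites with zero testable samples → `no_testable_samples`.

Defaults (75 bp / QUAL 20 / depth 20 / 1% / α = 0.05) suit 75 bp paired-end
RNA-seq; all are flags. Missing GT with AD present counts as "no data":
the binomial null is defined only for a called heterozygote.

## Synthetic data generator

`simulate.generate` emulates a multi-sample RNA-seq call set at the level
the detector consumes — per-site allelic depths — not reads. Defaults
describe one tissue of a moderate cohort: 23 samples, heterozygosity 0.3
per sample/site, per-call depth ~ negative binomial (mean 50, size 5;
variance = mean + mean²/size) truncated at 1 read, reflecting overdispersed
RNA-seq coverage (a Poisson switch exists for closed-form checks); 14% of
variants carry true ASE at allele proportion 0.7. The skewed allele is
chosen per variant with equal probability, so planted ASE does not fake a
cohort-wide reference bias. Homozygous calls carry 1% cross-contamination
reads so the minor-fraction filter path is exercised. Contaminant classes
(indel, near-indel SNP placed 30–75 bp from a planted indel, multiallelic,
low-QUAL, caller-failed, all-homozygous) are planted at configurable rates
— zero by default — and recorded per site in a truth table together with
the expected filter outcome, which lets tests compare the accounting to
ground truth *exactly*; for that to hold, clean sites force their first
sample to be a testable heterozygote. Identical seeds give byte-identical
VCFs. `spike_reference_bias` re-draws heterozygous depths with a chosen
reference proportion to emulate mapping bias against an unmasked genome.

What passing tests on these fixtures do **not** show: robustness to
genotyping error, allele-depth miscounting, correlated samples, reference
bias that varies by sequence context, or overdispersion of the allelic
ratio itself (true counts here are exactly binomial given depth; real ASE
data are often beta-binomial). The binomial test's anti-conservatism under
such overdispersion is a known limitation of this model class.

## Summaries

* **ASE frequency** = significant samples / denominator, binned into ten
  left-closed right-open intervals over [0, 1] (last bin closed; exactly
  0.1 falls in "0.1–0.2"). The denominator defaults to the variant's own
  testable-sample count, with an option for the run's total sample count;
  the per-variant table reports both.
* **Direction concordance**: per variant, the majority fraction among
  significant samples; the global figure pools significant results over
  variants with ≥ 2 significant samples (single-sample variants are
  trivially 100% and would inflate it).
* **Reference-allele ratio**: mean of ref/(ref+alt) over all testable
  pairs, in percent; ≈ 50% on unbiased data.
* **Gene ASE score** = (ASE SNPs / informative SNPs) × 100 per gene and
  tissue; the global score is the unweighted mean over tissues where the
  gene has ≥ 1 informative SNP, with threshold counts at ≥ 50 / ≥ 80 /
  = 100%. Variants mapping to several genes count once per gene.
* **Annotation enrichment**: per category, a 2×2 Fisher exact test of
  category-vs-rest against ASE-vs-background, BH-adjusted within the
  grouping. Background defaults to *all* informative variants (the ASE set
  is a subset; the test is then of composition shift), with an
  informative-minus-ASE option for a disjoint contrast. A category found
  only among ASE variants reports an infinite fold change with a finite p.
* **Group association**: per variant, Fisher exact test of a binary sample
  label against per-sample significance; degenerate margins give p = 1.

## Concordance

Both call sets are filtered first (panel: SNP call rate ≥ 97% among shared
samples, inclusive; RNA-seq: caller verdict, 75 bp indel proximity,
QUAL ≥ 20, and per-genotype AD-sum ≥ 20 — shallow genotypes are masked
missing rather than dropping the site). Sites join on (chrom, pos) when
their allele sets agree; genotypes compare as unordered multisets of allele
*sequences*, which makes the comparison phase-blind and harmonises a
ref/alt swap between files without explicit recoding. Strand flips are not
resolved (both call sets are assumed on one reference build). A pair's
denominator counts sites where both calls are non-missing. `matched`
pairing computes same-named pairs; `all_pairs` fills the matrix for the
shuffled control, whose off-diagonal mean should sit far below the
diagonal.

## Numerical and I/O choices

Report files are TSV with a single provenance comment line carrying the
tool version and effective parameters — deliberately no timestamp, so a
rerun with identical inputs is byte-identical. Floats render at 6
significant digits; nulls as `NA`. The VCF reader streams records in
constant memory, preserves GT/AD fields byte-exactly through a round trip,
rejects symbolic alleles, and treats an AD whose length disagrees with the
allele count as missing (with a warning) rather than guessing an
alignment. Phasing is retained for serialisation only; all logic uses the
allele-index multiset.

## Problem sizes used in the shipped checks

The calibration tests use 200 replicates of 500 variants × 10 samples at
depth 50 for null FDR control, 300 + 700 variants at depth 100 for power,
and fixtures of 400–2000 sites elsewhere — sizes at which Monte-Carlo
standard errors are small enough for 3-SE acceptance bands while the whole
suite stays interactive. The acceptance script mirrors these at the same
order of magnitude.
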