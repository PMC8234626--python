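# Methods

## Terminal fragments and polyA-site models

Annotations are isoform-centric and hard-wire upstream splicing choices to
3′ ends, so quantifying whole isoforms confounds APA with splicing. The
quantification unit is therefore the transcript's *terminal fragment*: its
last two exons in transcription order (`rnaseq` mode) or the 3′-terminal
300 nt of the spliced transcript (`3pseq` mode, matching the genomic
footprint of oligo-dT-anchored 3′-end reads, whose fragments are ~200–300 nt).
A single-exon transcript contributes the whole transcript — the natural
degenerate case of "last two exons" — and a spliced length under 300 nt
likewise yields the whole transcript in `3pseq` mode.

Transcripts tagged `mRNA_end_NF` (ill-defined 3′ ends, GENCODE dialect) are
always removed; restriction to `protein_coding` biotypes is optional.
Annotations are indexed once with gffutils; the index is cached next to the
GFF3 and keyed on the file checksum, so a modified or truncated annotation
never silently reuses a stale index.

Fragment 3′ ends are clustered into polyA sites by single linkage on the
sorted end coordinates with an inter-end gap of ≤ 25 nt (inclusive). Chaining
means a cluster can span more than 25 nt transitively; this is the simplest
deterministic reading of "ends within 25 nt of each other" and is invariant
to input order. Sites are ordered in transcription direction (ascending
coordinate on `+`, descending on `−`) and indexed m = 0 … n−1. A site's
representative end is its most distal member end — a fixed,
expression-independent choice — and its terminal exon is the exon containing
that end.

Structure classification compares the sites' terminal exons, treating exon
records from different isoforms as the same exon when their genomic intervals
overlap (annotations rarely repeat identical exon records across isoforms):
all pairs overlapping → tandem UTR (TUTR); no pairs overlapping → alternative
last exons (ALE); otherwise mixed, which requires n > 2. Genes with a single
site have no defined class and are NA throughout ψ analysis.

All input/output coordinates are GFF3-style 1-based inclusive. Genes whose
transcripts disagree on strand or chromosome are dropped with a warning.

## ψ

Per sample, a site's abundance is the sum of its member fragments' TPM
(`rnaseq`) or estimated counts (`3pseq`); fragments missing from a quant
table count as zero with a warning, since quantifiers drop duplicate or
zero-length sequences. Abundance is scaled by m/(n−1) and
ψ = Σ scaled / Σ unscaled, so ψ ∈ [0, 1] with 0 = exclusive proximal and
1 = exclusive distal usage, for any number of sites.

The expression filter is per sample: a gene whose summed site abundance is
below the threshold (default 5) in a sample is NA in that sample. In `3pseq`
mode the same threshold applies to summed counts — the filter is stated in
TPM terms for RNA-seq, and applying it to counts preserves the
minimum-evidence intent; it is configurable. There are no pseudocounts: zero
total abundance is NA, never 0/0. ψ is kept at full precision internally and
printed with six decimals.

## Differential testing

Per gene, the full model `ψ ~ condition (+ covariates)` is compared with the
null lacking only the condition term (covariates retained) by a
likelihood-ratio test, p from χ² with 1 df since condition is a single binary
indicator. Fits use maximum likelihood (REML would invalidate the LRT).
When a replicate-pairing column is supplied, a random intercept per pairing
group is included (statsmodels MixedLM), falling back to OLS when the mixed
fit is singular or fails — recorded per gene in `fit_status`. By default each
sample is its own group, the random intercept is unidentifiable, and the fit
is OLS; on simple two-condition designs this makes the LRT a monotone
transform of the two-sample t statistic, which is the intended behaviour.

Small-sample calibration: with three replicates per condition the asymptotic
χ²(1) reference is anti-conservative — on null simulations roughly 13% of
genes reach p < 0.05 at the OLS path (and more if a pairing random intercept
is forced on unpaired samples). This is a property of the asymptotic LRT at
n = 6, not of the implementation; the null-uniformity test therefore asserts
approximate uniformity (Kolmogorov–Smirnov D < 0.2) rather than exact
calibration, and benchmark false-discovery proportions should be read with
this in mind.

Genes are tested only when ψ is non-NA in every design sample; untested genes
carry a reason code. Degenerate fits (zero variance, non-convergence) yield
p = 1 with a flag, never an exception; a negative log-likelihood difference
(optimiser noise) also clamps to p = 1, and p is floored at machine epsilon.
Benjamini–Hochberg step-up is applied once across tested genes; Δψ is the
second condition level's mean minus the first's, with the orientation
recorded in the results metadata. A covariate perfectly confounded with
condition (rank check on the design matrices) is a configuration error.

## Synthetic benchmark

The generator reproduces the reference benchmark design: 5000 two-site genes
(1250 shifted distal, 1250 shifted proximal, 2500 unchanged), two conditions
with three replicates each. Gene expression is a flat Dirichlet draw over
genes scaled to TPM (sum 10⁶; marginals ≈ Beta(1, n−1), near-exponential).
ψ values are rejection-sampled from Uniform(0, 1) per gene until the
direction's constraint holds: positive genes need min ψ_B − max ψ_A ≥ 0.1,
negative genes the mirror image, control genes every pairwise |Δψ| < 0.25
(within and across conditions). The sampler is vectorised, capped at 10⁵
candidate draws per gene, and an infeasible margin (≥ 1) is a configuration
error. The uniform proposal is an assumption — the original procedure states
only "randomly sampling until the conditions are met".

Gene TPM splits between sites as (1−ψ, ψ) — the exact inversion of the
two-site ψ formula — and within a multi-transcript site by a flat Dirichlet
partition. Target counts are round(TPM × transcript length × scale), with the
scale set per sample so total counts match `library_size` (default 5 × 10⁷
reads per sample). Quant tables are emitted directly — read-level simulation
and external quantifiers are out of scope — with TPM recomputed from the
rounded counts (count/length, renormalised), so tables are internally
consistent and carry realistic rounding error; recovered ψ differs from the
truth by ~10⁻³ at default depth, well inside the 0.02 round-trip bound the
tests assert. Optional Poisson noise around target counts is off by default,
keeping fixtures byte-reproducible from the seed.

The toy annotation assigns each gene two single-transcript sites laid out as
tandem UTR or ALE (configurable mix, default 50:50; the original benchmark's
mix is unstated) on alternating strands, minus-strand genes mirrored, so the
full annotation path — strand handling, grouping, classification — is
exercised end to end. All randomness flows from one seed through independent
substreams per stage (direction, expression, ψ, splits, structure, noise), so
changing the structural mix does not perturb ψ assignment.

What the generator does **not** emulate: read-level sampling noise and
quantifier misassignment between isoforms sharing sequence, library-prep
biases, more than two polyA sites per gene, expression differences between
conditions, and annotation errors. Passing benchmark tests therefore
demonstrates correctness of the ψ/test machinery under clean abundance
estimates, not robustness to quantifier error on real libraries.

Caller evaluation follows the benchmark's rule: q < 0.05 calls a gene
positive or negative by the sign of its reported Δψ; everything else —
including genes the caller could not test — is called control. The 3×3
confusion matrix yields per-class sensitivity and precision; the summary
"affected sensitivity" requires the called direction to match the truth, and
the false-discovery proportion counts direction errors as false discoveries.

## Directionality and coupling summaries

α is the fraction of significant (q < FDR) genes with positive Δψ, under the
caller-declared orientation; genes with Δψ exactly 0 are excluded from
numerator and denominator (direction is undefined for them), and N = 0 yields
an explicitly flagged undefined score. The binomial test against 0.5 is exact
and two-sided by doubling the smaller tail, capped at 1 — the common
convention where the original analysis names only "binomial p values".

ρ correlates expression change with Δψ by Spearman rank (average ranks on
ties), either across genes for one sample pair or across sample pairs for one
gene; β applies the same statistic to a regulator's expression change versus
the per-pair median Δψ over significant genes. All require ≥ 3 complete pairs
and non-degenerate variance, else they return flagged-undefined scores. The
CLI computes expression change as log2 fold change with a TPM ≥ 5 filter in
both samples; rank invariance makes the log choice immaterial to ρ itself.

## Problem sizes used in tests

The statistical suites run on 300–500-gene fixtures with three replicates per
condition (the benchmark's replicate design at a reduced gene count, which the
vectorised generator and OLS-path testing make near-instant), the full
5000-gene reference design for generator-level checks, and 20–60-gene
fixtures for pipeline smoke tests. The acceptance script regenerates the full
5000-gene design.

## Known limitations

- The LRT's small-sample anti-conservativeness (above) inflates raw
  significance at n = 6; with many strong effects BH largely absorbs this,
  but near-threshold calls on small designs deserve caution.
- Classification depends on annotation exon boundaries; overlapping terminal
  exons that are biologically distinct last exons will be read as tandem UTR.
- `3pseq` mode trusts the quantifier's count assignments within the 300-nt
  windows; no read-position model is applied.
- The per-sample expression filter can leave a gene testable in one
  comparison and not another; genes must be non-NA in all design samples to
  be tested.
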