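# Methods

This note documents the models behind `pirnahd`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions that tests rely on.

## Coordinate and sequence conventions

All alignments are ungapped and use 0-based, half-open `[start, end)`
reference coordinates. A minus-strand read stores its *leftmost* reference
coordinate in `start`; its biological 5′ end is therefore at `end − 1`.
Reads are DNA-alphabet strings (T, not U); the RNA/DNA distinction is
presentation-only. FASTQ qualities are written as constant `'I'` and
ignored on input — no stage of the analysis is quality-aware.

## Synthetic small-RNA libraries

Reads are drawn in three classes with a configurable mix (default 30%
miRNA, 20% siRNA, 50% piRNA, apportioned by largest remainder so class
counts always sum to the requested read count). miRNA-class reads are
prefixes of the mature miRNA references; siRNA (21 nt) and piRNA reads are
substrings of TE consensus sequences on either strand. Default length
profiles are conventional rather than fitted — no empirical per-class
length distribution was available — with the piRNA support on 23–31 nt and
a broad mode at 26 nt.

**Ping-pong structure.** A configurable fraction of piRNA reads is emitted
as sense/antisense pairs. The sense read's 5′ start *s* is drawn uniformly
and the antisense 5′ end is placed at *s* + 9, so every truth pair overlaps
by exactly 10 nt by construction. The 1U/10A biases are optional
(`None` = off): when set to *b*, the targeted base (antisense position 1 →
T; sense ping-pong partner position 10 → A) is forced with probability *b*
and replaced by a uniformly chosen other base with probability 1 − *b*, so
the *marginal* base frequency equals *b* exactly and a configured bias of
0.8 is recoverable as an empirical fraction of 0.8. The 1U bias applies to
every antisense piRNA read (paired or not) because the uridine preference
is a property of piRNA biogenesis generally, while 10A marks ping-pong
sense partners specifically. With biases off and `error_rate = 0`, every
read re-maps to its truth placement with zero mismatches — the closure
property the mapper tests rely on.

**Adapters and errors.** A 3′ adapter (default the common TruSeq-style
small-RNA adapter sequence) is appended to a configurable fraction of
reads — truncated to `max_read_length` when one is set, and skipped when
the insert already fills the budget — and per-base substitution errors are
injected afterwards, so errors can corrupt the adapter too.

**What the generator does not emulate:** genomic piRNA clusters and their
promoter structure, transposition dynamics or copy-number evolution,
indels (the pipeline discards indel alignments by construction, so
simulating them would only remove reads), ligation biases, 2S rRNA
contamination, and multi-mapping ambiguity between near-identical
families (reference families are random sequences and effectively
orthogonal). Passing tests therefore demonstrate correctness of the
*computations* under a clean generative model, not robustness to every
artefact of real libraries.

## Read processing

Adapter trimming removes the read suffix matching a prefix of the adapter
(minimum overlap 3 nt, at most `floor(0.1 × L)` mismatches for a length-L
match, longest match preferred), mirroring the defaults of standard
trimmers. Reads shorter than 5 nt after trimming are discarded.

Mapping considers every ungapped placement of the read and of its reverse
complement at every offset of every TE reference and reports the single
minimum-Hamming-distance placement within the mismatch budget (tiers 3 and
6). `N` never matches. Ties are broken deterministically — family name
lexicographic, then + strand before −, then smallest start — replacing the
pseudo-random multi-hit choice of seed-based aligners so that outputs are
exactly reproducible and testable. The implementation one-hot encodes
reads and reference windows and scores all placements of a length class
with one matrix product; an independent naive double-loop oracle in the
test suite checks exact agreement of the reported placement.

miRNA subtraction removes every read with an ungapped placement on any
miRNA reference at ≤ 1 mismatch (either strand). The stage order is fixed:
trim → length filter → miRNA subtraction → TE mapping; the library size
used for normalization is the read count surviving all three filters.

## Quantification and differential abundance

Counts are tallied per (family, library) within a length window — piRNA
23–31 nt by default, siRNA 20–22 nt. The piRNA window upper bound is
genuinely ambiguous in small-RNA practice (31 vs 32 nt conventions
coexist), so the window is an explicit argument everywhere with 23–31 as
the default. RPM = count / library size × 10⁶, with optional replicate
averaging per line.

The differential test is a deliberately simplified voom:

1. log₂-CPM = log₂((count + 0.5) / (library size + 1) × 10⁶);
2. per-family least squares on (intercept, resistance covariate);
3. lowess (span 0.5) of √(residual sd) on mean log₂-CPM, evaluated at each
   cell's fitted value (flat extrapolation beyond the data; a floor of
   10⁻⁴ keeps weights finite on degenerate perfect fits);
4. observation weights = (predicted √sd)⁻⁴, i.e. inverse predicted
   variance;
5. weighted least squares per family; t = slope/se with n − 2 df;
   Benjamini–Hochberg across families.

There is no empirical-Bayes moderation of the residual variances, so t
statistics are ordinary; validation is by simulation (type-I error within
[0.03, 0.07] under a permuted-covariate null, ≥ 80% BH-adjusted power for
a 2 log₂-unit two-group effect at 12 libraries), not by matching any
external implementation's output. Resistance enters as a continuous
covariate (1 − mean dysgenic proportion); a precision-weighted two-sample
Welch contrast (`group_contrast`) is provided for extreme-line
comparisons.

## Ping-pong signature

For one family, every (plus-strand 5′ end *s*, minus-strand 5′ end *e*)
pair contributes its overlap *o* = *e* − *s* + 1 to a histogram over
bins 1–20. `read-pairs` weighting counts reads with multiplicity (the
default, appropriate for raw libraries); `position-pairs` counts distinct
coordinate pairs (for collapsed-read inputs). The statistic is

z₁₀ = (c₁₀ − mean(B)) / sd(B),  B = {c₀ : o ∈ [1, 20], o ≠ 10},

with the sample (ddof = 1) standard deviation; z₁₀ is undefined (reported
as NaN) when sd(B) = 0. The z > 3 reporting threshold is a documented
convention — ping-pong presence is usually reported qualitatively — and
its operating characteristics are measured by simulation: ≤ 5% false
positives over 200 null libraries, ≥ 90% detection with a 0.3 paired
fraction and 5,000 piRNA reads. 1U/10A fractions use the *sequenced* read
bases (mismatches included), since the biases act on the piRNA molecule,
not the reference.

## Cross statistics

The two-sided Fisher exact p sums hypergeometric probabilities of all
tables with the observed margins whose probability is ≤ that of the
observed table (relative tolerance 10⁻⁷), computed with cached
log-factorials; the all-zero table has p = 1. The probability-ordering
rule is the default convention; doubling the one-sided p is not offered.

The maternal-line effect is a grouped-binomial logistic regression fitted
by IRLS (deviance change < 10⁻⁸ or 50 iterations; the deviance trace is
exposed and non-increasing), with lexicographic reference levels for line
and tester subline. The test is the likelihood-ratio χ² between
`~ line + subline` and `~ subline`, df = lines − 1. Coefficients beyond
±15 flag quasi-separation; the p-value is still reported with the flag.

Screen concordance is Pearson's r with the standard t transform
(t = r√((n−2)/(1−r²))). Extreme-line classification takes the k lowest and
k highest mean dysgenic proportions, lexicographic on ties (flagged).

## qPCR analysis

Expression is relative to the reference gene only:
expr = E^−(Ct_target − Ct_ref) with amplification efficiency E = 2.0 by
default (configurable; no standard-curve estimation). Splicing efficiency
is spliced/total expression, undefined when total is zero. A calibrator
ΔΔCt baseline is deliberately omitted — ratios and ANOVA terms are
invariant to it.

Box-Cox λ maximizes the profile log-likelihood
−(n/2)·ln σ̂²(y_λ) + (λ−1)Σln x on the grid [−2, 2] step 0.01. Note an
identifiability caveat: when the coefficient of variation of the data is
small (data far from zero *relative to their spread*), the profile
likelihood is nearly flat and λ̂ is uninformative; the validation
experiments use normal data with CV ≈ 0.2, where λ̂ concentrates near 1
(empirical sd ≈ 0.16 at n = 500).

The splicing ANOVA uses sequential (type-I) sums of squares in the fixed
order direction + temperature + line, so each factor is assessed after the
preceding ones; on a single two-level factor it reduces exactly to the
pooled-variance t test (F = t²).

## Pipeline, seeding, and problem sizes

One global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence.spawn`, so any stage can be rerun in isolation
and identical (seed, config) pairs produce byte-identical outputs and
manifest checksums. The manifest records per-library read counts at every
stage (non-increasing through the filters, mapped counts nested across
mismatch tiers) and SHA-256 checksums of all outputs.

The validation experiments run at desk scale by design: libraries of
500–6,000 reads over 1–5 random TE families of 0.6–2 kb, 12 lines × 2
replicates × 2,000 reads for the end-to-end study, 100–500 simulation
replicates per operating characteristic. These sizes put binomial
standard errors well inside the asserted bands while keeping the whole
suite in the low tens of seconds; all of them scale up linearly through
the same APIs.

## Known limitations

* The mapper is exhaustive and exact but O(reads × reference length);
  it is meant for consensus-sized references (kb), not genomes.
* Best-hit-only reporting: multi-mapping reads are assigned
  deterministically, never apportioned or randomized.
* The voom variant's weights are estimated from as few families as the
  reference set provides; with < 4 families the mean–variance trend
  degenerates to a constant.
* No gapped alignment, no quality-aware processing, no TMM/quantile
  normalization, no random-effects modelling of replicates.
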