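# Methods

This note documents the models, parameter choices and numerical decisions
behind `velcroseq`, and what the synthetic-data tests do and do not
establish about real data.

## Data model and units of analysis

The unit of testing is a 200-nt genomic window advanced in 100-nt steps
(trailing truncated windows are kept; `drop_partial` removes them). Windows
overlap, so adjacent windows share fragments; the analysis treats windows
as independent tests, which overstates the effective number of tests by
roughly the width/step factor. This mirrors common practice for
sliding-window differential analyses and is deliberately not corrected;
interpretation of absolute discovery counts should keep it in mind.

A *fragment* is the mate-pair union interval of a properly paired
alignment — leftmost start to rightmost end, including the unsequenced
insert — or the aligned blocks of an unpaired (possibly spliced) record.
Each fragment increments every window it overlaps by ≥ 1 nt exactly once.
Counting is unstranded; coordinates are 0-based half-open internally, GTF
is read 1-based inclusive, bedGraph written 0-based half-open. Windows are
annotated with every region (5′ UTR / ORF / 3′ UTR) of any overlapping
isoform; generic `UTR` features are oriented by strand relative to the
transcript's CDS span; the primary label uses the fixed priority
5′ UTR > ORF > 3′ UTR. Windows whose total count across all samples is
below `min_total = 30` are discarded (a total of exactly 30 is kept);
library sizes remain the pre-filter column sums.

## Normalization

TMM factors use trim proportions 0.30 (M) and 0.05 (A), delta-method
weights `1/w = (N−K)/(NK)` summed over the two samples, and a reference
sample whose upper quartile of CPM is closest to the mean upper quartile.
Windows with a zero count in either sample are excluded from M/A; no
pseudo-counts are used inside TMM. Factors are rescaled to geometric mean
one, so depth lives entirely in the library size and factors encode
composition. Ranking for the trims is done on values rounded to 9 decimals
so that exact ties (e.g. two-point M distributions on synthetic data) are
not split by floating-point noise; if the double trim leaves nothing, the
A-trim and then both trims are relaxed, in that order. Normalized tracks
divide counts by `N_i f_i` and scale to CPM; each window's value is written
on its leading step-sized bin to keep bedGraph intervals disjoint.

## Linear modeling and variance moderation

log-CPM uses a prior count of 0.5 and the `N_i f_i + 1` denominator. The
design is intercept + condition (treatment = the non-WT level), no
replicate blocking. Observation weights follow the mean–variance trend
construction: per-window OLS residual sd on the quarter-root scale
(`sqrt(s_g)`) is smoothed against average log₂ count by lowess with span
0.5 (3 robustifying iterations); each observation's predicted sd at its
fitted log-count gives weight `sd⁻⁴`, with linear interpolation clamped at
the trend ends. Below 10 windows the smoother is unsupported and constant
weights are used with a warning.

The variance prior (d₀, s₀²) is estimated by moment matching on
`log s_g²` using digamma/trigamma closed forms, with a Newton solver for
the trigamma inverse. Two degenerate branches are handled explicitly: all
variances identical → d₀ = ∞ with s₀² equal to the common value (posterior
sd = observed sd, normal-limit p-values); non-positive excess dispersion →
d₀ = ∞ with the bias-corrected geometric-mean scale. `moderate=False`
disables the prior (d₀ = 0) and reproduces the classical t exactly.
Moderated two-sided p-values come from Student t on d₀ + d_g df.

An important calibration fact, verified numerically: moderated p-values
are *exactly* uniform under the hierarchical null (per-window variances
drawn from the scaled inverse-χ² prior) but only approximately uniform for
homoscedastic data, where the hierarchy is misspecified. Calibration tests
therefore simulate the hierarchical null, and aggregate per-seed
Kolmogorov–Smirnov p-values with a second-level KS test (per-seed KS
p-values are themselves uniform under calibration; a miscalibrated stage
drives them all to zero).

## Empirical null and local fdr

Defaults: 150 equal-width bins spanning the data range (no tail trimming),
natural cubic spline basis with 25 df (knots at quantiles of bin
midpoints), Poisson regression fitted by direct L-BFGS maximum likelihood —
the IRLS route oscillates harmlessly but indefinitely when tail bins are
empty, so the optimizer was chosen for a clean convergence criterion. The
fitted density is clamped below at its smallest positive binned value when
evaluated at arbitrary z.

The null is estimated by truncated-normal maximum likelihood on the fixed
central interval `[δ_start − 2σ_start, δ_start + 2σ_start]` with
`(δ_start, σ_start) = (−0.5, 1.0)`: with N₀ of N statistics in the
interval, the likelihood is binomial in the interval mass θ times the
truncated normal for the central z; `p₀ = θ / P_null(interval)`, capped at
1. Optimization is Nelder–Mead on (δ, log σ, logit θ) with up to 10
jittered restarts. Correctness is defined by parameter recovery on known
mixtures (e.g. 0.85·N(0,1) + 0.15·N(3,1) at n = 10⁴ recovers the non-null
fraction within ±0.04), not by bit-agreement with any particular package.

`fdr(z) = min(1, p₀ f₀(z)/f(z))` is the posterior null probability;
"enriched" additionally requires z > δ₀ (one-sided, the gain-of-binding
direction). Both 1 − p₀ (primary) and the integrated posterior non-null
mass `mean(1 − fdr)` are reported. The fdr-≤-threshold rule is a local-fdr
filter, not a tail-area FDR; on planted mixtures the realized false
discovery proportion of the flagged set stays below the threshold's
vicinity (≤ 0.10 is what the tests assert at threshold 0.05). The spline
tail beyond the ~99.5th percentile of z sits on empty bins and is not
informative; monotonicity of fdr on the right flank is asserted only
within the data-supported range.

## Region and gene-set overrepresentation

The region test uses the Pearson χ² statistic on the 3×2 region ×
enriched table with a permutation null (default B = 10⁵, giving p
resolution 10⁻⁵): enriched flags are permuted across windows with labels
fixed, which in PRIMARY_LABEL mode (each window counted once, by its
primary label) is sampled exactly as a multivariate hypergeometric draw of
per-region enriched counts — fast and identical in law to explicit
permutation. MULTI_LABEL mode (a window contributes to every region it
overlaps) uses explicit permutations. `p = (1 + #{χ²_perm ≥ χ²_obs})/(B+1)`
is never zero. The per-region fold is
`P(enriched | region)/P(enriched)`; note that a planting *propensity* of r
toward 5′ UTRs yields a measured fold below r, because the overall rate
rises too — the generator and tests invert this relation when a target
fold is wanted.

Gene-set enrichment takes as positive set the genes with ≥ 1 window at
fdr ≤ 0.05 and as background the genes with ≥ 1 tested window. Per term,
the one-sided hypergeometric p is computed after intersecting the term
with the background; the permutation FDR redraws random positive sets of
the same size (default 10³ permutations) and averages
`#{p_perm ≤ p_term}/#{p_obs ≤ p_term}`, capped at 1. Reported terms
satisfy obs/exp ≥ 2, observed ≥ 3 and FDR ≤ 0.05. Term hierarchies are
treated flat; graph-aware decorrelation is out of scope.

## k-mer complementarity

All distinct substrings of `reverse_complement(ES)` for 4 ≤ k ≤ 8 are
enumerated; a k-mer at reverse-complement offset j maps to ES positions
`[L−j−k, L−j)`. Occurrence counting includes overlapping matches (the
conservative superset; flagged in output metadata) and is implemented as a
rolling base-4 encoding with per-sequence bincounts, verified against a
brute-force scan. The rank-sum test compares enriched 5′ UTR windows
against *all* 5′ UTR windows (the enriched ones included — the comparison
the pipeline defines); p-values are two-sided, by full enumeration of
group assignments with midranks when both groups have ≤ 10 values and by
the tie-corrected normal approximation with continuity correction
otherwise. The location parameter is the Hodges–Lehmann median of pairwise
differences (positive = higher in enriched). FDR is Benjamini–Hochberg
across all k-mers of all lengths jointly; significance requires FDR ≤ 0.05
and a positive shift; maps onto candidate UTRs show k ≥ 5 only.

Window sequences for the k-mer stage are genomic (unspliced) subsequences;
a transcript-coordinate re-analysis can be done by passing transcript
FASTA to the same functions.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions of the design it
emulates: 3 replicates per condition, planted non-null fraction 0.157,
planted log₂ fold change 2.0 (constant; a gamma mode with the same mean is
available since the true effect-size distribution of such experiments is
unknown), negative-binomial counts with dispersion 0.1 (the standard
RNA-seq count model; no model is implied by the analysis itself), window
expression log-normal around e^4.6 ≈ 100 with sd 0.7 on the log scale, and
fragment lengths normal around a median of 246 nt (sd 30, truncated to
[40, segment length]).

Two generators serve different purposes. `generate_counts` draws pure NB
marginals per window — the right input for calibration and recovery tests
of the statistical stages. `generate_dataset` is fragments-first: genes
live one per contig (plus strand by default; strand handling is exercised
by hand-built GTFs in the tests), fragments are placed uniformly within
their gene segment, and the count matrix is obtained by counting those
fragments with the same overlap rule as the counting module, so emitting
them as SAM and re-counting reproduces the matrix exactly. An exact round
trip from an *arbitrary* count matrix is impossible over overlapping
windows (any fragment overlapping an interior window also overlaps a
neighbour); the direct mode of `generate_alignments` for matrices without
stored fragments is therefore approximate and documented as such.
Enrichment in the fragments-first generator is planted per gene segment
(with a configurable 5′ UTR propensity), so window-level truth marks every
window overlapping an enriched segment — window truth fractions exceed the
segment-level planting rate.

Planted k-mers are written at non-overlapping positions into the genomic
5′ UTRs of enriched genes; background UTRs are i.i.d. uniform nucleotides.
The default ES sequence is synthetic (a fixed 60-nt string); all k-mer
machinery accepts any ES FASTA.

What passing tests show: the arithmetic of windowing/counting/filtering is
exact; TMM, the moderated-t stage and the empirical null are calibrated
and recover planted parameters under the stated models. What they do not
show: robustness to features real libraries have and the generator omits —
UMI duplication, sequencing error, spliced fragments spanning introns,
multi-isoform annotation, rRNA background, and correlated biological
replicates. Conclusions about real data rest on the method, not on these
simulations.

## Problem sizes and determinism

Test and acceptance runs use ~20,000 windows for pipeline-level checks,
10⁴ statistics for density/null recovery, 10⁵ permutations for the region
χ², and 100 seeds for k-mer calibration — sizes chosen so the full suite
runs in a few minutes on one CPU while keeping Monte-Carlo error well
below the asserted tolerances. Every stochastic component takes an
explicit seed; `scripts/acceptance.py` derives all of its sub-seeds from a
single `--seed`, and identical seeds reproduce byte-identical generator
output and identical pipeline manifests.
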