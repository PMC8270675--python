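# velcroseq

Differential ribosome-binding analysis of sliding mRNA windows, for
RIP-seq-style experiments in which pools of mRNA fragments are recovered
with two kinds of ribosomes — for example yeast ribosomes carrying a
humanized 18S rRNA expansion segment (hES9S) versus wild-type (WT)
ribosomes — and the question is *which mRNA regions bind differentially,
and whether that binding tracks sequence complementarity to the expansion
segment*.

The package is aimed at computational biologists who have per-sample
alignments (SAM/BAM) or a precomputed window-count matrix for a small
replicated two-condition design, and who want a tested, reusable and fully
synthetic-data-verifiable implementation of the analysis chain:

1. **Window quantification** — fragments (mate-pair union intervals) are
   counted over 200-nt windows advanced in 100-nt steps; windows with a
   count total below 30 across all six samples are discarded; windows are
   annotated as 5′ UTR / ORF / 3′ UTR by any-isoform overlap against a GTF.
2. **TMM normalization** — per-sample composition factors from the doubly
   trimmed (30% on M, 5% on A), precision-weighted mean of log-ratios
   against a reference sample, rescaled to geometric mean 1.
3. **Moderated t-statistics** — per window, log₂-CPM
   `y_gi = log2((K_gi + 0.5)/(N_i f_i + 1) · 10⁶)` is fit by weighted least
   squares on intercept + condition, with observation weights from a lowess
   mean–variance trend (predicted sd⁻⁴). Residual variances are shrunk
   toward a scaled inverse-χ² prior fitted by digamma/trigamma moment
   matching, giving `s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g)` and
   `t̃_g = β̂_g/(u_g s̃_g)` on `d₀ + d_g` degrees of freedom.
4. **Empirical-null local fdr** — the marginal density f(z) of the t̃
   statistics is fitted by Poisson spline regression on a 150-bin histogram
   (spline df 25); a normal null N(δ₀, σ₀²) and null proportion p₀ come
   from truncated-normal maximum likelihood on the central interval
   (started at δ = −0.5, σ = 1.0); each window gets
   `fdr(z) = min(1, p₀ f₀(z)/f(z))` and is flagged enriched when
   fdr ≤ 0.05 and z > δ₀.
5. **Region and gene-set overrepresentation** — a permutation χ² test of
   region × enrichment independence, and per-term one-sided
   hypergeometric tests with a permutation FDR; reported terms satisfy
   obs/exp ≥ 2, observed ≥ 3 and FDR ≤ 0.05.
6. **k-mer complementarity** — every distinct substring (4 ≤ k ≤ 8) of the
   reverse complement of the expansion-segment sequence is counted (with
   overlaps) in 5′ UTR window sequences; enriched versus all 5′ UTR windows
   are compared by Wilcoxon rank-sum tests with Benjamini–Hochberg FDR
   across all k-mers jointly; significant k-mers have FDR ≤ 0.05 and a
   positive Hodges–Lehmann location shift, and those with k ≥ 5 are mapped
   onto candidate 5′ UTRs.

A first-class synthetic-data generator produces every input the pipeline
consumes — GTF/FASTA annotation, paired-end SAM alignments whose re-count
reproduces the generated count matrix exactly, negative-binomial window
counts with planted enrichment, and 5′ UTR sequences with planted
ES-complementary k-mers — so every stage is testable without any download.

## Worked example

`examples/04_empirical_null_local_fdr.py` simulates a study-scale
experiment (20,000 windows, three replicates per condition, 15.7% of
windows truly enriched at log₂FC = 2) and runs the statistical chain:

```
windows tested: 20000
empirical null: N(-0.415, 0.995^2), p0 = 0.841
estimated non-null fraction: 15.9% (planted: 15.6%)
windows flagged at local fdr <= 0.05: 2953
precision of the flagged set against the planted truth: 0.998
```

The fitted null mean is negative because, with ~16% of windows gaining
material in one condition, normalization shifts the log-ratios of the null
windows slightly down — exactly the situation the empirical (rather than
theoretical) null is there to absorb. The estimated non-null fraction
1 − p₀ recovers the planted 15.6%, and essentially every flagged window is
a true positive.

The other scripts in `examples/` each demonstrate one capability:
simulation and round-trip counting, TMM + moderated t, region and gene-set
overrepresentation, k-mer complementarity, and the orchestrated end-to-end
run. A thin CLI (`velcro simulate|count|normalize|diffbind|locfdr|regions|
geneset|kmers|tracks|run`) wraps the same library functions for shell use.

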