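# Methods

This note documents the statistical models implemented in `popadapt`, the
choices made where the methods literature leaves room, and what the synthetic
data generator does and does not emulate.

## Data model

Genotypes are biallelic SNPs coded as alternate-allele counts (0/1/2) with
missing calls as NaN; each locus carries the unigene (transcript contig) it
sits on and a 1-based position within that unigene, because the reference is
a transcriptome — coordinates restart on every unigene and all windowed
statistics are anchored per unigene.  Read-depth filtering is an upstream
caller responsibility; the matrix-level filters are call rate strictly
> 0.5, minor allele frequency strictly > 0.05 (computed on called alleles
only), and removal of monomorphic loci.  Missing genotypes are excluded from
every frequency denominator; they are mean-imputed per locus only where a
complete matrix is mathematically required (PCA, Hellinger/RDA, LFMM).

## Diversity and differentiation

* **π** per segregating site is the gene-copy unbiased heterozygosity
  (n/(n−1))(1 − p̂² − q̂²); sites are grouped into non-overlapping 1000-bp
  windows per unigene, window π = Σπ_site / window length, and the reported
  value is the mean over windows containing at least one SNP (the convention
  of windowed VCF-based π tools).
* **H_O / H_E / F_IS**: per-locus observed heterozygote fraction and
  unbiased H_E, averaged over loci polymorphic in the *total* dataset so all
  populations are summarized on one locus set; F_IS = 1 − mean(H_O)/mean(H_E)
  (the ratio-of-means convention of `hierfstat::basic.stats`, not the mean of
  per-locus ratios).
* **F_ST** is the Weir & Cockerham (1984) variance-component estimator:
  per-locus components a (among populations), b (among individuals within
  populations), c (within individuals), multilocus θ = Σa/Σ(a+b+c).
  Negative estimates are reported as-is — the estimator is unbiased around
  zero and truncation would bias comparisons.  Pairwise significance comes
  from 1000 permutations of individuals across the pair, with
  p = (1 + #extreme)/(1 + #permutations) throughout the package.
* **AMOVA** is two-level and gene-copy based: sums of squares are computed
  from allele indicators summed over loci (equivalent to squared Euclidean
  distances on two-column allele profiles, and to allele-frequency AMOVA for
  biallelic data).  df_among = k−1; the per-population copy counts c_i are
  per-locus called-copy counts averaged over loci, so with complete data
  c_i = 2n_i exactly and df_within = Σc_i − k; under missingness the df may
  be non-integral.  n0 = (Σc − Σc²/Σc)/(k−1), Va = (MSA−MSW)/n0, Vb = MSW,
  Φ_ST = Va/(Va+Vb).  With identical populations SS_among = 0 and the
  unbiased Va estimate is −MSW/n0 < 0 whenever within-population variance
  exists; this is reported, not clamped.  Degenerate all-constant data
  report Φ_ST = 0 by convention.
* **PCA** centres genotypes at 2p̂ and scales by √(2p̂(1−p̂)) (missing values
  mean-imputed first); axis variance fractions are relative to the total
  variance of the scaled matrix.

## Expression statistics

FPKM = 10⁹·C/(N·L).  Analyses run on log2(FPKM+1).  Per unigene, values
above Q3 + 1.5·IQR are masked, with quartiles as Tukey hinges and only the
upper fence active (the filter targets extreme expression, not low
expression).  The masking is single-pass: fences are not recomputed after
masking, so a second application can mask a few additional borderline points
(mask growth is monotone; retention is idempotent).  A unigene is retained
when at least half of the individuals have log2 value > 0 (inclusive
comparison).

E_p(gene, population) is the arithmetic mean FPKM over the population's
non-missing individuals (log2 is display-only for E_p).  E_d(gene,
population) is the mean absolute pairwise difference of log2(FPKM+1) among
individuals — the expression analogue of π.  The originating method
description does not print the E_d formula; this definition is the
package's own, isolated in one function so it can be swapped.  E_p
similarity between two populations is the mean Pearson correlation over all
cross-population individual profile pairs.  The π–E_d correlation per
population uses Pearson r over unigenes with a two-sided permutation test.

## Directional relative migration

For each unordered pair a hypothetical migrant pool takes the unweighted
mean of the two populations' allele frequencies.  Gene flow *into*
population X is scored from the two-deme differentiation between X and the
pool: Nm = 0.25(1/G_ST − 1) directly, or the reciprocal of G_ST / Jost's D
for those measures; all directed scores are divided by the global maximum.
H_S and H_T are plain (uncorrected) heterozygosities, deliberately: the
pool is a deterministic average of the pair's *sample* frequencies rather
than an independent sample, so "unbiased" n/(n−1) corrections systematically
push H_S above H_T at the 5–12-individual population sizes of this design
and clamp every pair at the ε floor.  Uncorrected, H_S ≤ H_T holds by
Jensen's inequality and rankings are stable.  Non-positive differentiation
(identical demes) is clamped at ε = 10⁻⁶ before reciprocals.  Bootstrap 95%
CIs resample individuals within populations and renormalize per replicate.
Nm and G_ST always rank edges identically (monotone transform); Jost's D can
legitimately reorder edges when within-deme diversity is strongly
asymmetric, because it normalizes by 1 − H_S.

## Outlier detection

The Bayesian scan models alternate-allele counts of locus i in population j
as beta-binomial with ancestral frequency p_i and dispersion
θ_ij = 1/F_ij − 1, where logit(F_ij) = δ_i·α_i + β_j.  Priors: p_i uniform,
β_j ~ N(−1, 1.8²), α_i ~ N(0, 1), inclusion indicator δ_i at prior odds
1:10.  The sampler is Metropolis-within-Gibbs, vectorized over loci, with a
fixed-dimension Gibbs-variable-selection move: excluded α are refreshed from
the prior, which leaves the same posterior as the reversible-jump sampler of
the reference method while being simpler to verify.  The within-population
allele frequency is marginalized analytically (beta-binomial), halving the
sampler dimension.  The posterior error probability is 1 − P(δ_i = 1 | data);
q(i) is the cumulative mean of PEPs in PEP rank order, and loci with
q < 0.001 are classified diversifying (α > 0) or balancing (α < 0).  A
split-chain disagreement heuristic (> 0.1 difference in inclusion
probabilities for > 5% of loci) warns on possible non-convergence.  Default
chain: 1000 burn-in + 3000 kept iterations thinned by 3 — calibration runs
showed zero false positives at q < 0.001 across 20 neutral island-model
datasets at this length.

## Sweep scan

Per unigene: multilocus Weir–Cockerham F_ST between the pooled focal and
background groups, and log2(π_background/π_focal) with per-unigene π as the
sum of per-site heterozygosities (the unigene length cancels in the ratio);
zero π is floored at half the smallest nonzero value.  Thresholds are the
empirical 95th percentiles and candidates must strictly exceed both.  The
two statistics are positively correlated on shared data, so the joint rate
under exchangeability (measured ≈ 0.006 across 100 replicates) modestly
exceeds the independence approximation top_frac² = 0.0025 while remaining
an order of magnitude below the marginal 5% rate.

## Environment association

* **VIF pruning** iteratively removes the variable with the largest
  VIF = 1/(1−R²) until all ≤ 10; exact ties drop the later-listed variable.
* **dbMEM**: great-circle distances, truncation at the longest
  minimum-spanning-tree edge with distant pairs set to 4× the truncation,
  Gower double-centring of −½d², eigenvectors with positive eigenvalues in
  eigenvalue order.  On a regular transect the leading MEM is the
  broad-scale sinusoid tracking position; strict monotonicity fails at the
  flattened tails, so tests assert the trend correlation instead.
* **RDA**: multivariate least squares of the Hellinger-transformed genotype
  matrix on centred predictors; R² = SS_fit/SS_total, adjusted by Ezekiel's
  formula with m = rank of the predictor matrix; global test by permuting
  response rows (999 by default); per-axis p-values compare each constrained
  eigenvalue with its permutation distribution (an approximate marginal
  test, not vegan's sequential test).  Perfect fits report pseudo-F = ∞.
* **Forward selection** adds the adjusted-R²-maximizing candidate, stopping
  when its Freedman–Lane partial-permutation p exceeds α = 0.05 or the
  model's adjusted R² would exceed the all-variable model's (the double
  stopping rule; the cap can be disabled).
* **Variation partitioning**: adjusted R² of Y~env, Y~geo, Y~env+geo gives
  [a] = [abc]−[bc], [c] = [abc]−[ab], [b] = [ab]+[bc]−[abc], [d] = 1−[abc];
  [b] may be negative (adjusted-R² arithmetic).  Pure fractions get partial
  permutation F tests (Freedman–Lane under the conditioning model).
* **LFMM** is the least-squares latent-factor formulation: minimize
  ‖G_c − UVᵀ − xbᵀ‖² with rank-K factors by alternating least squares,
  then per-locus z-scores of the environmental effect given the factors.
  Ten repetitions with jittered initializations are combined by the median
  z; genomic control rescales by λ = median(z²)/0.456 before two-sided χ²
  p-values (significance at p < 0.005; K defaults to 4, matching an
  admixture-based choice, and is a config input).  With ~10 sampling sites
  the environmental design has ~10 effective units however many individuals
  are genotyped, which bounds attainable power: a truth-level oracle
  (regressing the *simulated* population frequencies on the environment)
  recovers ~9.6/10 planted loci at logit effect 2.5 per environmental SD and
  only ~5/10 at effect 1.5; the implementation reaches ~9.1/10 at effect
  2.5, i.e. near the information limit, and the power test is run there.
* **Mantel** tests (scikit-bio backend) correlate lower triangles with a
  one-sided (greater) permutation p; IBD uses haversine distances in km,
  IBE Euclidean distances on the first five PCs of the standardized
  environmental variables.

## Niche overlap

Suitability surfaces are normalized to sum to one; D = 1 − ½Σ|p₁−p₂| and
I = 1 − ½Σ(√p₁−√p₂)².  The identity test pools occurrences, re-splits at
the original sizes, refits the (pluggable) suitability model — default: a
Gaussian KDE on a user grid; full climate-envelope modelling is out of
scope — and declares differentiation one-tailed when the observed statistic
falls below the null's 5th percentile.

## Synthetic data

The generator reproduces the *statistical* structure the analyses assume:
ten populations of 5–12 diploids (defaults 12,12,8,12,11,12,12,12,12,5 —
108 individuals), Balding–Nichols drift with a target F (default 0.25,
where the Weir–Cockerham estimator has a known expectation), an optional
minority of loci whose logit frequencies track a standardized environmental
variable at the population's site, environments drawn from a Gaussian
process with exponential covariance exp(−d/300 km) on great-circle distances
plus independent noise, and log2-scale expression with gene baselines
(Gamma-distributed, right-skewed), population effects (SD 0.4) and
individual noise (SD 0.5), optionally coupled negatively to per-gene allelic
diversity to exercise the π–E_d analysis.  It does **not** emulate linkage
disequilibrium, coalescent genealogies, read-level sampling noise,
batch/library effects in expression, or non-equilibrium demography; passing
tests therefore demonstrate estimator correctness under the island-model
idealization, not robustness to those real-data complications.
Determinism: one integer seed drives independent child streams for
coordinates, environment, genotypes and expression, so identical
configurations are bit-identical.

## Problem sizes and numerical conventions

Simulation-based tests use 500–2000 loci and 80–120 individuals — large
enough that Monte-Carlo error sits well inside the asserted tolerances
(e.g. multilocus θ at 2000 loci varies by ≈ ±0.005 across seeds against a
±0.03 band), small enough to keep the suite fast.  Permutation p-values are
always (1 + #extreme)/(1 + N).  Monomorphic loci contribute zeros to F_ST
components; loci with no called copies are errors.  All randomized
procedures accept explicit seeds and are reproducible bit-for-bit.
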