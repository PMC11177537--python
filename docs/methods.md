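# Methods

This note documents the models, estimators and design choices behind
`amlink`, and what the synthetic validation does and does not establish.

## The scientific setting

In a family cohort ascertained through an affected child, positive
assortative mating (AM) shows up three ways:

1. **Phenotypic AM** — spouses' quantitative trait scores correlate.
2. **Ancestry-related AM** — spouses' positions on genetic-ancestry axes
   (principal components) correlate, because mate choice is geographically
   and culturally structured.
3. **Genetic consequences** — under either form of AM (or plain population
   admixture), genotype frequencies depart from Hardy–Weinberg proportions
   at ancestry-informative loci (intra-locus correlation, Wright's F), and
   long-range linkage disequilibrium appears between unlinked loci whose
   allele frequencies differ between ancestral groups (inter-locus
   correlation, cross-chromosome D²).

The package implements the measurement pipeline for all three and a
forward simulator that generates cohorts in which each effect has a known
magnitude.

## Estimators

**Wright's F.** For a bi-allelic marker with observed heterozygote count
`n_oAa` and Hardy–Weinberg expectation `n_eAa = 2·p̂(1−p̂)·n`,
`F = 1 − n_oAa/n_eAa`. Monomorphic markers (expectation zero) are flagged
undefined and excluded from means, with contribution counts reported.
Pooling two panmictic subpopulations with frequencies `p₁, p₂` gives the
Wahlund expectation `F = (p₁−p₂)²/(4·p̄·q̄)`; the test suite checks the
estimator against this closed form to ±0.01 over 1000 markers.

**Two-locus EM.** Haplotype frequencies `(p_AB, p_Ab, p_aB, p_ab)` are
estimated from unphased genotype pairs by EM: only double heterozygotes
have ambiguous phase, resolved each E-step with weight
`p_AB·p_ab/(p_AB·p_ab + p_Ab·p_aB)`. Initialization is linkage
equilibrium at the observed allele frequencies; convergence is a maximum
absolute frequency change < 1e-10 within 1000 iterations (non-convergence
is flagged, the pair retained). The implementation is batch-vectorized
over all SNP pairs with active-set compression, which is what makes the
resampling design tractable on one CPU. An independent coarse-to-fine
grid search over the haplotype simplex verifies that EM attains the
likelihood maximum to 1e-6 on random small tables.

**D².** `D = p_AB − p_A·p_B`, squared so it is invariant to allele
relabeling at either locus. Even at linkage equilibrium the estimator has
a sampling floor `E[D̂²] ≈ p_A q_A p_B q_B/(2n)`; with a few hundred
diploid samples that floor (~1e-4 scale products / 1e3) dominates any
individual pair, which is why the analyses only ever interpret *averages
over many pairs* and *contrasts between SNP sets* of the same size.

**The resampling contrast.** Markers are first LD-pruned (greedy
left-to-right, r² > 0.1 within 500 kb), then each iteration randomly
thins the list to a ≥ 500 kb spacing, ranks the thinned set by |PC1|
loading, and contrasts the top-K ("highly ancestry-informative") against
the bottom-K set: mean F per role, and mean D² over all
different-chromosome pairs within each set (same-chromosome pairs are
excluded entirely). Iteration seeds derive as `seed + iteration`. A Welch
two-sample t-test compares the top vs bottom iteration means per role and
statistic.

**A caveat on the iteration t-test.** The iteration means are not
independent: every iteration re-samples the same cohort and the same
fixed loading ranking. The t-test therefore quantifies variability of the
*subset selection*, not of the cohort, and its statistic grows without
bound in the iteration count whenever the full-pool top-vs-bottom
difference is not exactly zero — which, in any finite cohort, it never
is. Consequently the procedure is anticonservative when interpreted as a
test over cohort replications; its p-values should be read as descriptive
of the contrast within the given cohort. The suite documents this
directly: a calibration check over 20 simulated no-structure cohorts
shows rejection well above the nominal rate, and is expected to fail.
Interpretation of positive findings should therefore lean on effect
magnitude and cross-role consistency, not the p-value alone.

**pTDT.** Per trio, deviation = (child − midparent)/sd(midparent), with
the sample (n−1) standard deviation of midparent scores across included
trios; a one-sample two-sided t-test compares the mean deviation to zero.
Under liability-threshold ascertainment with h² > 0, probands are
expected to over-inherit trait-increasing alleles (positive deviation)
while unaffected siblings stay near zero.

**Odd/even-chromosome θ.** Scores built from disjoint chromosome-parity
variant sets are regressed on each other with the opposite parity's top-20
PCs (from LD-pruned SNPs, r² > 0.1, > 1 Mb apart) as covariates:
`S_o = θ·S_e + PCE₁..₂₀` and `S_e = θ·S_o + PCO₁..₂₀`. Scores are
standardized first so θ is on a correlation scale. Both estimates are
reported plus their inverse-variance-weighted mean (a plain mean if a
regression is an exact fit). AM on the score itself makes θ positive in
the offspring generation; ancestry-only AM with ancestry-independent
weights leaves it null once PCs are included.

**Spousal correlations and comparisons.** Quantitative traits use
Spearman's rank correlation (exact permutation p for n ≤ 8, the t
approximation above — enumerating beyond 8! permutations buys nothing at
cohort sample sizes); PCs and polygenic scores use Pearson. Confidence
intervals use the Fisher z transform, which for Spearman is an
approximation and labeled as such. Two independent strata are compared
with `z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`. The power rule
`n = ⌈((z_{1−α/2}+z_pow)/atanh r)² + 3⌉` gives the minimum stratum size;
at r = 0.3, α = 0.05, power 0.8 this is 85, which the pipeline uses as
the floor for subgroup analyses.

**Quality control.** Fixed order: sample missingness (> 5% removed) →
variant call rate (≥ 95% kept) → extended-LD region exclusion → MAF
(≥ 0.01 kept) → exact Hardy–Weinberg test (p ≥ 1e-5 kept) → Mendelian
error rate (> 5% removed). MAF and the HWE test use founders only;
offspring of the same families are not independent draws from the mating
pool, and including them would bias both. The HWE test is the plain
two-sided exact test (no mid-p), summing probabilities of heterozygote
counts no more probable than the observed one, conditional on allele
counts. Genotypes at Mendelian-inconsistent cells are not zeroed; the
filter acts at the variant level only.

**Ancestry PCA.** Dosages are standardized per variant by mean `2p̂` and
scale `√(2p̂(1−p̂))` with `p̂` from the fitting set (cohort founders plus
reference panel); missing values impute to the post-standardization mean
(zero). Children are projected, never fitted, so sibling/parent structure
cannot distort the axes. Loading signs are fixed (largest-magnitude entry
positive) for reproducible rankings. Assignment uses per-population
centroids on (PC1, PC2): a sample is target-like only if strictly closer
to the target centroid than to every contrast centroid on *both* axes;
ties exclude. A family is retained only when every genotyped member
passes. The two-round design — continental contrast panel for inclusion,
within-continent subpanels for the working PCs and loadings — mirrors
standard practice; the round-2 |PC1| loadings drive everything downstream.

## The simulator

* **Divergence**: Balding–Nichols — ancestral `p ~ U[0.05, 0.95]`,
  subpopulation frequencies Beta-distributed around `p` with parameter
  Fst. Default Fst 0.005 represents within-continent substructure and is
  a configuration choice, not a claim; analyses that need a visible
  ancestry axis at desk scale use 0.01–0.1.
* **Genome geometry**: variants are assigned round-robin to 22
  chromosomes with uniform positions, default 8 Mb per chromosome for a
  2000-SNP panel. Chromosome length scales down with the panel so marker
  spacing stays array-like (~90 kb): the 500 kb thinning step must force
  a genuine random subsample, as it does on a real array, or the
  resampling design degenerates into re-analyzing one fixed SNP set.
* **Founders**: admixture proportion `α ~ Beta(0.5, 0.5)` (variance
  0.125). This was set so the induced parental cross-chromosome D² lands
  on the order of 1e-5, the magnitude reported for real family cohorts;
  loci within a founder share its α, which is the generative source of
  admixture LD.
* **Mating**: a Gaussian-copula coupling on a latent score combining
  normal scores of α and of the liability, with weights `a²:b² =
  rho_ancestry:rho_trait` and couple latent correlation `rho_ancestry +
  rho_trait`. This guarantees the target spousal correlations (to within
  small non-normal-margin attenuation) without modeling a mate-search
  mechanism — the analyses measure correlations, not mechanisms.
* **Transmission**: each parent transmits one allele per locus
  independently (no recombination map). The downstream analyses only use
  markers ≥ 500 kb apart or on different chromosomes, where background
  linkage is negligible; AM-induced LD does not require linkage.
* **Ascertainment**: liability = genetic value (scaled to variance h²)
  plus normal noise; "affected" means exceeding the 1−q founder quantile
  (default q = 0.02). Simplex-like cohorts keep families with exactly one
  affected of two children, drawing candidate families in batches until
  the target count is reached — emulating how a simplex collection
  samples from a much larger population. CI/ID-like group labels are an
  independent exchangeable split, so stratum comparisons have a true null.
* **Reference panels**: round-1 contrast panels come from an independent
  Balding–Nichols divergence at Fst 0.15 (continental scale), because
  contrasts placed on the cohort's own admixture axis would exclude most
  admixed families under the strict both-axes centroid rule; round-2
  subpanels sit at α ∈ {1, 0.75, 0.5, 0.25, 0} along the within-continent
  axis.

**What the simulator does not emulate**: genuine LD decay and haplotype
blocks (loci are exchangeable given ancestry), multi-generation AM
equilibria, X-linked variation, genotyping batch/platform artifacts,
geographic stratification, and de novo variation. Passing tests therefore
establish that the estimators measure what they claim under a known
generative model with realistic magnitudes — not that real-cohort effect
sizes will be reproduced.

## Numerical choices

* EM tolerance 1e-10, cap 1000 iterations; log-likelihood computed from
  the multinomial genotype model at the converged frequencies.
* PCA via dense SVD (panels are desk-scale); `k` reduced with a warning
  when above rank.
* Ranking ties (equal |loading|) break by genomic coordinate; thinning
  and iteration seeds are derived deterministically from the run seed.
* `sd(midparent)` uses the n−1 denominator.
* Degenerate inputs raise typed errors rather than returning NaN:
  correlations on constant vectors, pTDT with zero midparent variance,
  residualizing a trait on itself.
* Monte-Carlo tolerances in tests are set from the binomial/normal error
  of the simulated sample sizes, not tuned to outcomes.

## Problem sizes

Desk-scale defaults — 2000 SNPs, 500 quartet families, 100 resampling
iterations, K = 100 — run each heavy analysis in tens of seconds on one
CPU and reproduce every qualitative signature: spousal PC correlation
tracking the generative rho, proband-only pTDT over-transmission,
null/positive θ behavior, and excess cross-chromosome D² at
ancestry-informative SNPs with parent-to-offspring attenuation. The
1000-iteration, K = 200/1000 presets from full-cohort practice remain
configuration options.
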