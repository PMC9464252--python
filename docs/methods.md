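# Methods

## Model and tests

A gene's qualifying rare variants enter a linear mixed model
y ~ N(Xα, σ²_e I + σ²_g φφᵀ) through the factor φ = φ(G), and the gene-level
test is H₀: σ²_g = 0 against σ²_g > 0. Because σ²_g sits on the boundary of
its parameter space, neither the score test nor the restricted
likelihood-ratio test (RLRT) has a standard chi-square null, and the package
treats the two stages differently.

**Score test.** With the OLS null fit (projection P = I − X(XᵀX)⁻¹Xᵀ,
residuals r = Py, σ̂²_e = rᵀr/(n−q)), the statistic is Q = rᵀφφᵀr / σ̂²_e and
its null law is Σ_s λ_s χ²₁ over the eigenvalues λ_s of φᵀPφ. Tail
probabilities come from Ruben's expansion of the quadratic form into a
nonnegative mixture of central chi-squares: with β = min λ, the survival
function is Σ_j a_j S_{χ²_{k+2j}}(q/β) with Σ_j a_j = 1, so the tail is
accumulated additively and the truncation error is bounded by the unassigned
weight. The series is run to absolute accuracy 1e-7 with a 5,000-term cap;
the Kuonen saddlepoint approximation takes over when the reported p is at
the accuracy floor (below 1e-6, where only a relative-accuracy method is
meaningful) or the series fails to converge (severely spread spectra). The
first implementation used Imhof characteristic-function inversion instead;
it could not reach 1e-7 for one- and two-eigenvalue spectra, whose inversion
integrand decays like u^{-1-k/2}, and was replaced.

**RLRT.** The restricted likelihood is profiled to one dimension: with
μ_s the nonzero eigenvalues of φᵀPφ, z_s the residual contrasts along the
corresponding directions and λ = σ²_g/σ²_e,

RLRT = sup_{λ≥0} [ (n−q)·log(rss₀ / D(λ)) − Σ_s log(1+λμ_s) ],
D(λ) = Σ_s z_s²/(1+λμ_s) + (rss₀ − Σ_s z_s²).

Under H₀ the z_s² are iid χ²₁ and the remainder is χ²_{n−q−K}, so the exact
finite-sample null (the Crainiceanu–Ruppert construction) is sampled by
drawing these chi-squares and taking the same supremum; sampler and direct
REML fits share the criterion by construction, and the test suite checks
that brute-force fits on fresh Gaussian data match sampler draws in
distribution. The supremum is taken over {0} ∪ 128 log-spaced ratios
spanning [1e−5, 1e5]/max μ_s, refined by 40 golden-section steps around the
grid argmax; statistics ≤ 1e−8 are snapped to the exact zero atom (the
boundary point mass is typically ≥ one half for small K, and distinct float
noise at the atom would otherwise corrupt two-sample comparisons).
Eigenvalues below 1e−10 of the maximum are discarded throughout.

**Two-stage sLRT.** Score tests run genome-wide; the RLRT and its 100 null
draws (per gene, per design) run only when the category's score p falls
below t = 0.1, so under the null the expensive stage runs for ~10% of genes
(a ~1/t speedup). Null statistics are pooled within (phenotype × variant
category × test-type × with/without pLOF) groups and summarised by
π·χ²₀ + (1−π)·a·χ²_d: π is the fraction of boundary zeros, and (a, d)
minimise squared differences between log empirical and log model survival
over the top-decile order statistics (started from moment estimates of the
nonzero component). The exact weighting of the original log-quantile
regression is not fully specified by its source, so this least-squares
variant is validated by a parameter-recovery test (π within ±0.01, a and d
within ±0.15 at 1e5 draws). p-values are 1 at a zero statistic, else
(1−π)·S_{χ²_d}(stat/a), floored at 1e−300. Pooling preserves the Bonferroni
FWER bound because, at equal per-gene draw counts, the pooled p equals the
mean of per-gene p's at every cutoff (an algebraic identity the suite
asserts), and the suite also checks that pooled and gene-specific mixtures
give near-identical p-values (r² of log₁₀ p ≥ 0.98 on a 200-gene null
study).

**Per-gene seeds** are SHA-256 hashes of (master seed, phenotype, gene,
design), truncated below 2³¹, so genome-wide runs are reproducible and
independent of gene order.

## Kernels and weights

Weights live in [0, 1]: ((1−SIFT)+PolyPhen)/2 for missense (both scores
required; rows missing either are excluded), max SpliceAI delta for splice,
max |p_alt − p_ref| over the R=8 RBP model outputs for RBP variants, and 1
for pLOF. Qualification thresholds are 0.8 (missense, with the rescue rule:
any variant at an amino-acid position anchored by a ≥0.8 variant of the same
gene qualifies), 0.1 (splice), 0.25 (RBP), all inclusive.

φ designs: max-weight collapsing (per-individual maximum weight over carried
variants, 0 for non-carriers); weighted linear φ = G_c diag(√w); local
collapsing φ = G_c diag(√w) C with one column per amino-acid position (entry
sign(v_i), all +1 here since the predictions are unsigned); and the RBP
kernel φ = G_c diag(√w) L with LLᵀ = S = Q∘R, Q the cosine similarity of
effect vectors and R the Gaussian positional similarity with
γ = −ln(0.5)/50² (0.5 at 50 bp, 0.0625 at 100 bp). S is factorized by
Cholesky with an escalating ridge (1e−8·tr(S)/m, ×10 up to 1e−4) because
variants sharing position and effect vector make S singular. Dosages are
mean-imputed per variant and mean-centered before any kernel is built; the
collapsed burden and the concatenated pLOF column are centered too (the
intercept absorbs the shift, and uncentered columns would displace the null
eigenvalues).

Per category: pLOF genes get the collapsing score test only. Missense genes
get collapsing + locally collapsing kernel; splice genes collapsing + linear
kernel; if either score p < t, both RLRTs run, and — when the gene has pLOF
variants — two joint designs as well (joint max-weight collapsing, and the
kernel factor with the collapsed pLOF column concatenated). Variants
annotated both splice and pLOF count on the pLOF side of joint designs only.
Genes without pLOF material skip the joint designs entirely: running them
would push an identical statistic through a second, independently fitted
pooled null group, and the Cauchy combination of the two noisy fits produced
spurious tail p-values in desk-scale null runs. RBP genes get a kernel-only
sLRT per strand (effect predictions are strand-specific); any pLOF variants
found in the RBP set are removed and the test repeated, with a flag. The
final per-gene p per track is the Cauchy combination of the category-only
and category+pLOF p-values where both exist, otherwise the single p.

Genomic inflation (λ_GC) is reported per (phenotype × category × test-type)
group from the genome-wide *score* p-values — the RLRT only runs on
triggered genes, so its p-values are not a genome-wide series and their
boundary atom at p = 1 would bias a median-based diagnostic.

## QC, filters, conditional tests

Variant QC: study-wide MAF ≤ 0.1% (computed once on the analysis sample,
folded, missing calls excluded from the denominator), call rate ≥ 90%, HWE
exact test p ≥ 1e−5 (full enumeration of heterozygote counts conditional on
allele counts, summing configurations no more likely than observed); all
violated thresholds are reported, not just the first. Ancestry pruning
compares each superpopulation's allele counts with the reference population
by two-sided Fisher exact tests, excluding variants with any p < 1e−5 or
with zero genotyped alleles in any population ("selectively missing" is
interpreted as zero genotyped alleles; no partial-missingness cutoff is
defined). Allele counts, not genotype counts, enter the 2×2 tables.

The MAF cutoff is a *study-scale* parameter: at biobank n it admits variants
with hundreds of carriers, while at desk-scale n (a few hundred samples) any
variant with a single carrier exceeds 0.1%. Desk-scale runs should relax
`maf_max` in the config; the simulator's MAF law is clamped to
[1/(2n), maf_max] and degenerates to all-singletons when maf_max ≤ 1/(2n).

Conditional tests augment X with the (centered) dosage of the most
significant nearby single variant (ties broken by distance to the gene
start), refit the null, recompute the RLRT, sample gene-specific null
statistics (250,000 by default; configurable, and far smaller in tests),
fit a gene-specific mixture on their top decile, and Cauchy-combine across
designs. A conditioning dosage collinear with the covariates is dropped
with a warning and the unconditional result returned flagged.

Phenotypes are rank-inverse-normal transformed ((rank−0.5)/n mapped through
the standard normal quantile), optionally within groups (e.g. sex);
phenotype-missing samples are dropped per phenotype, covariate-missing
samples globally. Bonferroni uses α = 0.05 over all emitted final p-values
across phenotypes, categories and test types.

## Synthetic data

The simulator generates what the tests assume and nothing more: per-variant
MAFs log-uniform on [1/(2n), maf_max] (a heavy singleton fraction emerges at
scale rather than being forced), Binomial(2, MAF) dosages with optional
missingness, four variant categories with weights in the ranges their
predictors produce (1 for pLOF, 0.8–1 missense, 0.1–1 splice, 0.25–1 RBP),
amino-acid position sharing among 20% of a gene's missense variants by
default, signed RBP effect vectors whose largest absolute entry equals the
weight, random strands, standard-normal covariates, and phenotypes
y = Xα + Gβ + ε with a configurable causal fraction, sign mixture and
gene-level variance explained (β rescaled so var(Gβ)/var(Gβ+ε) hits the
target; the null mode sets β = 0).

It deliberately omits linkage disequilibrium, population structure,
relatedness and genotyping artifacts. Calibration and FWER results on this
generator therefore show that the statistical machinery is correct under the
model's own assumptions — they do not certify robustness to stratification
or differential missingness in real cohorts, which is what the ancestry
pruning and call-rate filters exist to blunt.

## Validation problem sizes

The statistical suite uses desk-scale sizes chosen to keep Monte-Carlo error
well inside each acceptance band: score calibration at n=500, g=5 over 1,000
null replicates; sampler-vs-direct equivalence at n=100, K=5 with 2,000
draws each; mixture recovery at 1e5 draws; pooled-vs-gene-specific agreement
on 200 genes (100 pooled draws per gene, 5,000 for the gene-specific fits,
mirroring the production asymmetry); trigger-rate and FWER checks on 2,000
simulated genes (FWER over 3 phenotypes and 20 seeds); power ordering over
500 replicates per regime at n=500, m=10, 2% gene variance explained, with 3
mixed-sign causal variants in the kernel-favoring regime and 8 same-sign in
the collapsing-favoring one.

## Known limitations

Quantitative traits only (no binary-trait variance-component tests); no
background polygenic random effect (samples are assumed unrelated, as after
kinship pruning); variants are not re-weighted by allele frequency by
design; VCF/BGEN ingestion is an extension point (PLINK bed/bim/fam only);
transcript selection and the upstream prediction models themselves are out
of scope — predictions arrive as tables, one pre-averaged score pair per
(variant, gene).
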