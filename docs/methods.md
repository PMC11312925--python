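# Methods

This note documents the statistical models behind `glycotwin`, the design
choices that were genuinely open, and what the synthetic-data generator
does and does not emulate.

## Preprocessing

Raw glycopeptide intensities are converted to relative abundances by
dividing each glycoform by the summed intensity of all glycoforms on the
same tryptic peptide, so each peptide panel is compositional (closes to 1
over non-missing entries; an all-zero panel becomes missing rather than
0/0).  Outliers are removed per trait in a **single pass**: mean and
sample SD (ddof = 1) are computed once from all non-missing values and
entries strictly more than k·SD away (default k = 4) are masked; a value
exactly on the boundary is retained, and a constant trait masks nothing.
Quantile normalisation is the rank-based inverse-normal transform: average
ranks r among n non-missing values map to Φ⁻¹(r/(n+1)).  The Blom offset
(r−3/8)/(n+1/4) is available as an option; the two differ by <0.01 SD at
n ≥ 100 and nothing downstream is sensitive to the choice.  The pipeline
order is fixed — normalise → outlier-mask → quantile-normalise — and each
stage is tagged on the table.

Derived traits are weighted sums or ratios of relative abundances on one
peptide, defined in a YAML schema.  The shipped definition set
(`data/derived_traits_example.yaml` and `standard_trait_definitions`)
covers the generic feature families — fraction sialylated / fucosylated,
mean sialic acids or hexoses per glycoform — and is illustrative:
site-specific published formula sets should be supplied through the same
schema.  Ratio traits with a zero denominator yield missing values (with a
logged count) rather than an error, since compositional zeros are expected
at small n.

## Mixed models

Covariate association and residualization use a linear mixed model with
fixed covariates and crossed random intercepts (plate, family).  The REML
criterion is profiled over the residual variance and optimized over the
log variance ratios; all linear algebra goes through the Woodbury identity
so the per-iteration cost is one Cholesky of a (total random levels)²
matrix, independent of cohort size.  Fixed-effect p-values are Wald
(normal), matching common mixed-model reporting for single coefficients.
Residualization subtracts both the fixed-effect fit and the BLUPs
(conditional residuals) and standardizes; with a zero variance estimate it
reduces exactly to OLS residuals.  The family term is a family-level
random intercept — this descriptive model does not distinguish MZ from DZ
covariance; that contrast is the twin models' job.

The Li–Ji effective number of tests scores the absolute eigenvalues of
the trait correlation matrix with f(λ) = I(λ≥1) + (λ−⌊λ⌋).  Eigenvalues
are rounded to 9 decimals first: the integer split is discontinuous at
whole numbers and floating-point noise would otherwise score an exact
duplicate block as 2 instead of 1.  Both the raw value and the rounded
integer (used as the Bonferroni denominator) are returned.  Correlation
networks keep an edge only when |ρ| > 0.25 *and* p clears the
class-specific Bonferroni bound (α/(N(N−1)/2) within a class of effective
size N; α/(N_A·N_B) between classes); p-values use the t approximation on
pairwise-complete n.

## Twin models

Univariate ACE: on a standardized trait, a twin pair is bivariate normal
with common variance σ² and co-twin correlation a²+c² (MZ) or ½a²+c² (DZ).
The likelihood is evaluated from per-zygosity sufficient statistics (pair
count and 2×2 scatter), making each evaluation O(1); σ² is profiled
analytically and the variance proportions are optimized on the bounded
parameterization s = a²+c² ∈ [0,1], t = a²/s ∈ [0,1], which enforces all
constraints without penalties.  Sub-models fix t = 1 (AE), t = 0 (CE) or
s = 0 (E).  Free-parameter counts (3/2/2/1) enter AIC = 2k − 2·logL; AIC
ties resolve toward fewer parameters.  Standard errors come from the
observed information of the profile likelihood via the delta method and
are reported as undefined at a boundary.  Covariate adjustment is
two-stage (OLS residualize, then fit the pair likelihood), keeping the
likelihood 2-variate.  Co-twin order is randomized once with a fixed seed
when pairing from tables; the likelihood is symmetric regardless.

Bivariate AE: pairs are 4-variate normal with within-person covariance
A + E and cross-twin block φA (φ = 1 MZ, ½ DZ), where A and E are 2×2
genetic and environmental covariance matrices parameterized by their
Cholesky factors (positive semi-definiteness by construction).
Likelihood-ratio tests fix, in turn, the genetic (A₀₁ = 0), environmental
(E₀₁ = 0) or phenotypic (E₀₁ = −A₀₁) cross-trait covariance and refer
2ΔlogL to χ²₁ — these correlations are interior parameters, so the naive
reference is asymptotically correct (verified by null calibration in the
test suite).  A trait paired with itself makes the 4×4 covariance
singular; this is detected and returned as a flagged degenerate fit with
unit correlations.  A shared-environment (bivariate ACE) extension is out
of scope: the shared-heritability arithmetic uses only h² and 1−h², so AE
is the natural default.

Shared heritability combines a bivariate fit as
COV_G = ρG·√h²ₓ·√h²ᵧ, COV_E = ρE·√(1−h²ₓ)·√(1−h²ᵧ),
h²ₓᵧ = COV_G/(COV_G+COV_E), zeroing a correlation whose LRT p-value is
strictly greater than 0.05 before the covariances are formed.  When the
two covariances have opposite signs the ratio leaves [0,1] and is flagged;
when both are zero it is undefined and reported as such.  Conditional
genetic covariance refits the bivariate model on residuals adjusted for
lead-SNP dosages and reports Aₓ·Aᵧ·ρG plus the proportion of the
unconditional value removed.

## Conversion ratios

Reaction pairs are substrate/product glycoforms on the same peptide
differing by exactly +1 in one residue type.  For a fixed type each
substrate has a unique product, so the pair graph is a union of ladders;
maximal paths of ≥ 2 steps are the conversion chains.  Ratios are
product/substrate on untransformed relative frequencies (outlier-masked,
never quantile-normalised — a monotone transform would be harmless for the
rank test but would change the medians/IQRs that are reported); a zero or
missing substrate yields a missing ratio, not infinity.  Consecutive steps
are compared with the Wilcoxon **signed-rank** test on individuals
measured in both steps — the paired variant is the default because the two
ratio distributions come from the same people; the rank-sum variant is a
flag.  The Bonferroni denominator is always the number of junctions
actually tested in the current run, reported alongside the p-values.

## GWAS

The association model is y = Xβ + gβ_g + u + ε with
cov(u) = σ_g²K: K is either the expected pedigree relatedness (1 within MZ
pairs, 0.5 within DZ pairs, block-diagonal by family) or an empirical GRM
XXᵀ/m on dosages standardized by √(2pq) (monomorphic SNPs are excluded —
they carry no relatedness signal; with in-sample allele frequencies the
GRM off-diagonals of a pair shrink slightly at small cohort size).
Variance components are estimated once per trait under the null by 1-D
REML over the heritable fraction in the eigenbasis of K and held fixed
across SNPs (the standard two-step approximation); each SNP then reduces
to a weighted regression of the rotated trait on the rotated dosage, with
Wald t statistics.  The effect allele is always the minor allele (dosages
flipped before testing).  Genomic-control λ is the median association χ²
over χ²₁'s median (≈0.4549).  Conditional scans iteratively add the top
genome-wide-significant SNP to the covariates and rescan the window until
nothing clears the threshold.  Per-SNP variance explained is 2pqβ² on the
minor-allele frequency; totals sum over the independent leads only.  A
signal replicates when the effect direction is concordant and the
replication p is strictly below α/m; replication betas are flipped onto
the discovery effect allele when allele labels are supplied, and tag-SNP
substitution is supported only through an explicit user-supplied map (no
LD reference panel is bundled).  Plate enters the GWAS as a fixed
covariate.  Genotype principal components can be supplied as covariates;
they are off by default for single-ancestry synthetic data.

## Synthetic cohort generator

The generator is first-class, tested code and defines the study
conditions for every recovery experiment.  Defaults mirror a large adult
twin registry: 513 MZ pairs, 615 DZ pairs, 167 singletons, 78% female,
ages uniform on 19–88, 25 plates assigned round-robin by family (so plate
is never confounded with zygosity).  Co-twins share age (twins are born
together) and MZ co-twins share sex.  Genotypes follow a parental-gamete
model: two Hardy–Weinberg parents per family, MZ twins share one sampled
genome, DZ twins draw independent gametes (expected dosage correlation ½);
MAFs are recomputed from realized dosages.  Traits decompose into SNP
effects on √(2pq)-standardized dosages, a polygenic pair-correlated
Gaussian (cross-twin correlation 1/½) rescaled so SNP + polygenic variance
equals a², a family-shared C, an independent E, and age/sex/plate effects.
The bivariate generator draws 4-variate pair vectors whose cross-twin
cross-trait covariance is φ·ρG·√(a²ₓa²ᵧ) plus shared-environment terms;
shared causal SNPs contribute βₓβᵧ to the genetic covariance and are
subtracted from the polygenic residual (a non-PSD residual is an error).
Glycoform panels use a logistic-normal allocation:
softmax(log π + λ·c·u + ε) with base composition π, latent trait λ,
coupling direction u = centred sialic-acid counts (coupling scale 0.5,
logit noise SD 0.2 — chosen so the softmax Jensen bias on a 30% target
composition stays below 0.01), scaled by a lognormal total intensity.
The realized proportions are recorded, so total-area normalisation
recovers the truth exactly and derived-trait recovery is testable to
machine precision.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium beyond family
structure, genotyping/imputation error, below-detection missingness in the
abundance table, batch effects richer than a plate random intercept,
population stratification, assortative mating or gene–environment
correlation (the ACE assumptions are exactly true in simulation), and
subclass mixing within shared peptide clusters (each glycoform panel is
one compositional unit).

## Problem sizes and numerics

Recovery experiments use 2000+2000 pairs (univariate and bivariate
recovery), 150 replicates of 1000+1000 pairs for AIC model-selection rates
(the per-replicate AE-win probability under true c² = 0 is ≈0.92, so the
rate is estimated with ~2% precision), 200 replicates of 150+150 pairs for
LRT null calibration, cohorts of 1000 individuals × 5000 SNPs for GWAS
calibration, and n = 4000 unrelated individuals for SNP-variance totals —
sizes at which every Monte-Carlo tolerance in the test suite corresponds
to ≳3 standard errors.  Optimizers: Nelder-Mead (LMM variance ratios,
2–3 parameters; bivariate twin start), L-BFGS-B (univariate twin, bounded),
BFGS polish (bivariate twin), bounded 1-D minimization (GWAS null);
non-convergence flags the fit rather than raising.  Twin fits are
evaluated from sufficient statistics, so likelihood evaluations are O(1)
in the number of pairs; the monitored best-so-far log-likelihood trace of
the LMM is non-decreasing by construction and asserted in tests.
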