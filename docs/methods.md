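# Methods

## Association models and score tests

For individual i with phenotype y_i and gene dosages x_i ∈ [0,2]^M, the
joint model is

    quantitative:  y_i = β₀ + β₁ E_i + β₂ PRS_i + ε_i
    binary:        logit P(y_i = 1) = β₀ + β₁ E_i + β₂ PRS_i

with predicted expression E_i = Wᵀx_i (no intercept; constants are
absorbed by β₀) and an LD-adjusted PRS (below).  The gene-level hypothesis
H₀: β₁ = β₂ = 0 is tested with the efficient score test at the
intercept-only null fit: with Z̃ the column-centered predictor matrix,
U = Z̃ᵀ(y − ȳ) and V = φ·Z̃ᵀZ̃, where φ = σ̂² = Σ(y − ȳ)²/n for a
quantitative trait (the MLE, dividing by n; the n vs n−1 choice is
asymptotically irrelevant but must be fixed) and φ = ȳ(1 − ȳ) for a
binary one.  The statistic UᵀV⁻¹U is χ² with df = number of predictors:
2 for the joint TWAS-PRS tests, 1 for TWAS (E alone) and for PRS_B/T/Q
(the PRS alone).  The efficient (centered) score is what makes the
analytic p agree with a permutation distribution (checked at n = 200
against 10⁵ permutations) and gives the exact identity
statistic = n·r² for one quantitative predictor.

Degenerate cases: a numerically singular V (e.g., collinear E and PRS) is
handled by an eigenvalue-thresholded pseudo-inverse (cut 1e−10·λ_max) with
df reduced to the numerical rank, with a warning.  Zero-variance
predictors or phenotypes are errors.  P-values are two-sided upper-tail
χ² probabilities, floored at the smallest positive double.

Covariates are handled by regressing the phenotype on [1, C] and using
the residuals as a quantitative trait in all methods — including binary
phenotypes with covariates, which become quantitative residuals.  Without
covariates, binary traits use the logistic-null branch directly.

## PRS weightings

From per-SNP marginal GWAS results (β̂_m, T_m, p_m): w_m = β̂_m (B),
w_m = T_m (T), or w_m = sign(T_m)·T_m² (Q).  Missing score statistics are
recovered from |T| = Φ⁻¹(1 − p/2) with the sign of β̂.  The B weights
carry phenotype-per-allele units while T/Q are dimensionless; the score
test is invariant to predictor scaling, so no re-standardization of the
PRS is needed.

## LD adjustment

R is the sample correlation matrix of the gene's genotypes *in the
analysis sample itself* (no external reference panel).  Genotype columns
are standardized to mean 0, variance 1 before applying the transform,
since R^(−1/2) is a whitening operator on standardized scores; the
truncated inverse square root keeps the smallest leading set of L
eigenpairs covering ≥ 99.9% of the trace (the comparison is a plain ≥
with no slack, eigenvalues sorted descending with stable ties), which
keeps the transform finite when the gene contains near-duplicate SNPs.
Eigenvalues in [−1e−8, 0) are treated as floating-point zeros and can
never be retained; anything more negative is an error.  Monomorphic SNPs
are dropped (with a warning) before R is formed, and missing dosages are
mean-imputed per SNP at load time.

## Allele harmonization

SNPs are matched across genotype, weight and summary files by identifier.
A record whose effect allele equals the genotype's *other* allele has its
weight/effect sign negated, which is equivalent to mirroring the dosage
(x → 2 − x); either representation yields identical test statistics, a
property the suite checks end to end.  Unresolvable allele mismatches
drop the SNP, and every action is listed in the alignment report.

## Expression weights

`fit_expression_weights` estimates cis-effects by elastic net
(mixing l1_ratio = 0.5, the convention of the standard TWAS weight
pipelines) on standardized genotypes, with the penalty chosen by seeded
5-fold cross-validation minimizing MSE; coefficients are back-transformed
to the per-allele scale so prediction uses raw dosages.  In the
simulation studies the weight vector plays the role of a pre-computed
weight file and is *not* refit per replicate.

## Simulation design

A synthetic pool of 10,860 haplotypes (the size of a phased panel of
5,430 individuals) stands in for real phased haplotypes, which cannot be
redistributed.  Within blocks of 5 SNPs a Gaussian copula with
exchangeable latent correlation ρ = 0.5 is thresholded at each SNP's
MAF quantile (MAF ~ U(0.05, 0.5)); blocks are independent.  An
individual's genotype is the sum of two haplotypes drawn uniformly with
replacement.  Default genes have M = 15, 37 and 64 SNPs.

The per-gene cis-effect vector is synthetic (labelled as such): sparse,
with max(2, ⌈0.2·M⌉) nonzero entries drawn N(0, 0.5²), emulating the
sparsity of elastic-net weight files — a dense random vector would make
predicted expression a proxy for the whole gene's genotype signal and
invert the intended contrast between TWAS and PRS.  Expression is
generated under a sparsified version of this vector ("max": the single
largest-|W| entry; "h": the two largest; ties to the lowest index — the
magnitude rule keeps strong negative eQTLs), while *prediction* always
uses the full vector, mirroring an analyst holding the pre-computed file.

True expression: E_i = Wᵀx_i + e_i with e_i ~ N(0, WᵀĈov(X)W), Ĉov from
the generated sample (ddof = 1), so the genetic fraction of expression
variance is ≈ 1/2.  Phenotype: y_i = β(aE_i + Σ_{j∈causal} x_ij) + ε_i
with ε ~ N(0,1), a = 1, and c = ⌈M·prop⌉ causal SNPs redrawn uniformly
per replicate (they may overlap the eQTLs).  Binary traits threshold the
quantitative phenotype at mean + 1 sample SD (prevalence ≈ 1 − Φ(1) ≈
16%), sampling from the population without case enrichment.

Each study cell draws, per replicate, an independent GWAS reference
sample of size N (from which per-SNP summary statistics are computed
fresh — summary-statistic noise is part of the design) and an independent
association sample of size n from the same pool.  Replicate seeds are
spawned from the base seed via `numpy.random.SeedSequence` with a
cell-specific spawn key (gene, N, β, prop, trait type hashed with CRC32),
so any cell reruns bit-identically in isolation.  Rejection rates are
exact fractions k/n_replicates, compared against the 95% binomial band
α ± 1.96·√(α(1−α)/n_replicates).

### Problem sizes

The default grid mirrors the full study (n = N = 5000, 1000 replicates
per cell; a cell of all seven methods takes roughly 10 s for the 15-SNP
gene).  The test suite runs the full-scale calibration cell at 1000
replicates and the power cells at 500 replicates with β = 0.05 (chosen to
put power mid-range, where method orderings are informative); smaller
smoke configurations use n = 200–1000 with proportionally wider CI bands.

### Sequential calibration check

Checking seven empirical sizes against a 95% band has a ~30% familywise
false-alarm probability even for a perfectly calibrated test.  The
calibration test therefore escalates: a method whose 1000-replicate rate
falls outside the band is re-measured on an independent 4000-replicate
stage, and the pooled 5000-replicate rate must fall inside the tighter
5000-replicate band (0.044, 0.056) — added precision, not added slack.

## What the generator does and does not emulate

It reproduces blockwise LD, realistic MAFs, haplotype-resampling
genotypes, the half-genetic expression model, and the two-path phenotype
model.  It does not reproduce real genes' heterogeneous LD (long-range
decay, uneven block sizes) or heterogeneous per-SNP effect sizes; under
the exchangeable-LD, equal-effect conditions the advantage of the
signed-squared weighting over the plain score weighting is smaller than
on real genes — PRS_Q and PRS_T are statistically comparable here, with
PRS_Q slightly behind at high causal proportions.  Passing tests
therefore establish calibration and the broad method ordering
(joint ≥ PRS-only ≥ expression-only, and power increasing in β, N and
causal proportion), not fine power differences on real LD.

## Known limitations

* LD is estimated from the analysis sample; a reference-panel option is
  future work.  No LD pruning/clumping is provided (the whitening
  transform replaces it by design).
* VCF dosages come from hard GT calls (ALT-allele count); the DS field,
  BGEN/PLINK formats and multi-allelic sites are unsupported.
* The elastic-net fitter is a convenience path; it covers single-tissue,
  cis-only weights with no BLUP/BSLMM alternatives.
* Wald and likelihood-ratio variants exist only as internal test oracles.
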