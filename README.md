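# twasprs

Gene-based association tests that combine genetically predicted gene
expression with new, LD-adjusted polygenic risk scores.

## The problem

Transcriptome-wide association studies (TWAS) test whether the component of
gene expression predictable from cis-SNPs is associated with a trait; they
lose power when SNPs act on the trait directly rather than through
expression.  Gene-level polygenic risk scores (PRSs) aggregate marginal
GWAS signal across a gene's SNPs, but a naive weighted sum double-counts
SNPs in linkage disequilibrium (LD) and depends on the choice of per-SNP
weights.  `twasprs` implements, for a gene with M SNPs:

* **Three PRS weightings** from GWAS summary statistics — `PRS_B` with
  w_m = β̂_m (marginal effect estimates), `PRS_T` with w_m = T_m (score/Z
  statistics), and `PRS_Q` with w_m = sign(T_m)·T_m², which up-weights
  strongly associated SNPs while keeping effect directions.  When only a
  p-value and the effect sign are available, |T| = Φ⁻¹(1 − p/2).
* **An LD adjustment**: with R the sample correlation matrix of the gene's
  genotypes and R = Σ_l λ_l e_l e_lᵀ its eigendecomposition (λ₁ ≥ … ≥ λ_M),
  the smallest L with Σ_{l≤L} λ_l / Σ_l λ_l ≥ 0.999 defines the truncated
  inverse square root R^(−1/2) ≈ Σ_{l≤L} e_l e_lᵀ/√λ_l, and the PRS is
  computed on whitened genotypes, PRS_i = wᵀ R^(−1/2) x̃_i.
* **Score tests**: the 1-df χ² score test for a single predictor (TWAS on
  predicted expression E_i = Wᵀx_i, or a PRS alone), and the 2-df joint
  test of H₀: β₁ = β₂ = 0 in y_i = β₀ + β₁E_i + β₂PRS_i + ε_i (logistic
  link for binary traits), giving the combined `TWAS-PRS_B/T/Q` methods.
* **A simulation engine** that resamples genotypes from an LD-structured
  haplotype pool, generates expression as E_i = Wᵀx_i + e_i with
  e_i ~ N(0, WᵀCov(X)W), phenotypes as y_i = β(aE_i + Σ_j x_ij) + ε_i, and
  binary traits by the liability threshold mean + 1 SD (≈16% prevalence),
  plus orchestration for type-I-error and power studies of all seven
  methods.

It is aimed at statistical geneticists who want gene-level tests from
individual-level genotypes plus GWAS summary statistics and eQTL weight
files, or who want to benchmark such tests under controlled simulations.

## Worked example

`examples/03_joint_test.py` simulates a 15-SNP gene whose phenotype has
both an expression-mediated and a direct genetic component (β = 0.05),
derives summary statistics from an independent GWAS sample of 5000, and
runs all seven tests on a fresh association sample of 5000:

```
      method     chi2  df          p
        TWAS     0.11   1  7.382e-01
       PRS_B     7.16   1  7.458e-03
       PRS_T     7.77   1  5.301e-03
       PRS_Q     9.52   1  2.038e-03
  TWAS-PRS_B     7.17   2  2.772e-02
  TWAS-PRS_T     7.83   2  1.992e-02
  TWAS-PRS_Q     9.63   2  8.112e-03
```

TWAS sees only the expression-mediated signal and misses the gene; the
PRS-based tests capture the direct genetic path, with the signed-squared
weighting (`PRS_Q`) sharpest here; the joint tests combine both sources at
the cost of one extra degree of freedom.  The other examples cover weight
construction (`01`), the LD whitening transform (`02`), type-I calibration
(`04`), and power curves (`05`).

A thin CLI wraps the same machinery:

```bash
twasprs test-gene --geno geno.vcf --pheno pheno.tsv \
    --weights weights.tsv --summary gwas.tsv --method twas-prs-q
twasprs type1 --config study.yaml --out type1.tsv
twasprs power --config study.yaml --out power.tsv
```

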