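"""Build the three PRS weightings (B, T, Q) from GWAS summary statistics.

Simulates a GWAS reference sample for a 10-SNP gene, computes per-SNP
marginal effects and score statistics, and prints the three weight vectors
side by side.
"""

import numpy as np

from twasprs import (build_weights, draw_expression_weights, make_expression,
                     make_phenotype, per_snp_summary, resample_genotypes,
                     select_causal, synthesize_haplotypes)

pool = synthesize_haplotypes(10, seed=1)
geno = resample_genotypes(pool, 5000, seed=2)
w_true = draw_expression_weights(10, seed=3, snp_ids=geno.snp_ids)
expr = make_expression(geno, w_true, seed=4)
causal = select_causal(10, 0.2, seed=5)
y = make_phenotype(expr, geno, causal, beta=0.05, seed=6)

summary = per_snp_summary(y, geno)
print(f"causal SNP indices: {causal.tolist()}")
print(f"{'snp':>6} {'beta_hat':>9} {'T':>7} {'p':>9} "
      f"{'w_B':>8} {'w_T':>7} {'w_Q':>8}")
wb, wt, wq = (build_weights(summary, s).w for s in "BTQ")
for i, snp in enumerate(summary.snp_ids):
    print(f"{snp:>6} {summary.beta_hat[i]:9.4f} {summary.t_stat[i]:7.2f} "
          f"{summary.p_value[i]:9.2e} {wb[i]:8.4f} {wt[i]:7.2f} {wq[i]:8.2f}")

# w_B are phenotype-units-per-allele effect estimates; w_T are the
# dimensionless score statistics; w_Q = sign(T) T^2 exaggerates the
# strongly associated SNPs (note the causal SNPs' |T| and how squaring
# separates them further from the noise SNPs).
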