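"""Type-I-error and power studies over the seven gene-based tests.

A *cell* of the study fixes a gene (its LD structure and cis-eQTL weight
vector), a GWAS reference sample size N, a total effect beta, a causal
proportion, and a trait type.  Each replicate then

1. draws an independent GWAS sample of size N from the gene's haplotype
   pool, generates its phenotype, and computes per-SNP marginal summary
   statistics (beta-hat, score statistic, p);
2. draws a fresh association sample of size n, generates true expression
   and the phenotype (beta = 0 under the null);
3. builds predicted expression from the gene's full weight vector and the
   three LD-adjusted PRSs (B/T/Q) from the replicate's summary statistics;
4. runs the seven score tests and records rejections at level alpha.

Empirical rejection rates are exact fractions k / n_replicates.  Replicate
seeds are spawned deterministically from the base seed so any cell can be
re-run in isolation, bit-identically.
"""

from __future__ import annotations

import logging
import math
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc, prs, simulate
from .assoc import METHODS
from .data import GenotypeMatrix
from .expression import ExpressionWeights, predict_expression

logger = logging.getLogger(__name__)


@dataclass
class GeneConfig:
    """Static description of one simulated gene.

    ``weights`` (the analyst's pre-computed cis-eQTL vector) and the
    haplotype pool are derived deterministically from the study seed when
    not given explicitly.  ``expression_scheme`` controls which entries of
    ``weights`` *generate* expression: 'max' keeps the single largest, 'h'
    the two largest, 'full' all of them.  Prediction always uses the full
    vector, mirroring an analyst who only has the pre-computed file.
    """

    name: str
    M: int
    blocks: list[tuple[int, float]] | None = None
    maf_range: tuple[float, float] = simulate.DEFAULT_MAF_RANGE
    n_hap: int = simulate.DEFAULT_N_HAP
    expression_scheme: str = "max"
    weight_scale: float = 0.5
    weights: ExpressionWeights | None = None


# the three genes of the simulation study: 15, 37 and 64 SNPs
DEFAULT_GENES = (GeneConfig("gene1", 15), GeneConfig("gene2", 37),
                 GeneConfig("gene3", 64))


@dataclass
class ExperimentGrid:
    """Grid of study conditions shared by the type-I and power runs."""

    methods: tuple[str, ...] = METHODS
    betas: tuple[float, ...] = (0.0,)
    N_list: tuple[int, ...] = (5000,)
    prop_list: tuple[float, ...] = (0.2,)
    n: int = 5000
    n_replicates: int = 1000
    alpha: float = 0.05
    trait_type: str = "quantitative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}")


@dataclass
class CalibrationTable:
    """Empirical rejection rates with the nominal-level confidence band."""

    table: pd.DataFrame
    ci: tuple[float, float]

    def all_within_ci(self) -> bool:
        return bool(self.table["within_ci"].all())


def ci_bounds(alpha: float, n_replicates: int) -> tuple[float, float]:
    """95% binomial CI for an empirical rate at the nominal level.

    ``alpha +/- 1.96 sqrt(alpha (1 - alpha) / n_replicates)``, each bound
    rounded to 4 decimals.  With alpha = 0.05 and 1000 replicates this is
    the familiar (0.0365, 0.0635) acceptance band.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    half = 1.96 * math.sqrt(alpha * (1.0 - alpha) / n_replicates)
    return (round(alpha - half, 4), round(alpha + half, 4))


def _stable_key(name: str) -> int:
    """Process-independent integer key for a gene name (CRC32)."""
    return zlib.crc32(name.encode()) % (2 ** 31)


def _gene_pool_and_weights(gene: GeneConfig, base_seed: int
                           ) -> tuple[simulate.HaplotypePool, ExpressionWeights]:
    """Gene-level fixtures, fixed across every cell of a study."""
    pool_ss, w_ss = np.random.SeedSequence(
        entropy=base_seed, spawn_key=(_stable_key(gene.name), 0)
    ).spawn(2)
    pool = simulate.synthesize_haplotypes(
        gene.M, block_structure=gene.blocks, maf_range=gene.maf_range,
        n_hap=gene.n_hap, seed=np.random.default_rng(pool_ss))
    if gene.weights is not None:
        weights = gene.weights
    else:
        weights = simulate.draw_expression_weights(
            gene.M, seed=np.random.default_rng(w_ss), scale=gene.weight_scale,
            snp_ids=pool.snp_ids)
    return pool, weights


def _cell_seedseq(base_seed: int, gene: GeneConfig, N: int, beta: float,
                  prop: float, trait_type: str) -> np.random.SeedSequence:
    key = (_stable_key(gene.name), int(N), int(round(beta * 10 ** 6)),
           int(round(prop * 10 ** 6)), 0 if trait_type == "quantitative" else 1)
    return np.random.SeedSequence(entropy=base_seed, spawn_key=key)


def _simulate_phenotype(geno: GenotypeMatrix, gen_weights: ExpressionWeights,
                        beta: float, prop: float, trait_type: str,
                        rng: np.random.Generator):
    expr = simulate.make_expression(geno, gen_weights, seed=rng)
    causal = simulate.select_causal(geno.n_snps, prop, seed=rng)
    y = simulate.make_phenotype(expr, geno, causal, beta=beta, a=1.0, seed=rng)
    if trait_type == "binary":
        y = simulate.dichotomize(y)
    return y


def run_cell(pool: simulate.HaplotypePool, weights: ExpressionWeights,
             gene: GeneConfig, *, beta: float, prop: float, n: int, N: int,
             trait_type: str, alpha: float, n_replicates: int,
             methods: tuple[str, ...], seedseq: np.random.SeedSequence
             ) -> dict[str, float]:
    """Rejection rate of each method in one study cell."""
    gen_weights = simulate.sparsify_weights(weights, gene.expression_scheme)
    rejections = {m: 0 for m in methods}
    want_expr = any(m.startswith("TWAS") for m in methods)
    want_prs = {s for s in prs.SCHEMES
                for m in methods if m.endswith(f"PRS_{s}")}
    for child in seedseq.spawn(n_replicates):
        rng = np.random.default_rng(child)
        # independent GWAS reference sample -> summary statistics
        g_ref = simulate.resample_genotypes(pool, N, seed=rng)
        y_ref = _simulate_phenotype(g_ref, gen_weights, beta, prop,
                                    trait_type, rng)
        summary = assoc.per_snp_summary(y_ref, g_ref)
        # fresh association sample
        g = simulate.resample_genotypes(pool, n, seed=rng)
        y = _simulate_phenotype(g, gen_weights, beta, prop, trait_type, rng)
        e_pred = predict_expression(g, weights).E if want_expr else None
        scores = {}
        if want_prs:
            common = [s for s in g.snp_ids if s in set(summary.snp_ids)]
            g_c = g.subset_snps(common) if common != g.snp_ids else g
            summ_c = summary.subset(common) if common != summary.snp_ids else summary
            r = prs.sample_correlation(g_c)
            transform = prs.ld_inverse_sqrt(r, snp_ids=g_c.snp_ids)
            adjusted = prs.adjust_genotypes(g_c, transform)
            for s in want_prs:
                scores[s] = prs.compute_prs(adjusted, prs.build_weights(summ_c, s))
        for m in methods:
            p_vec = scores.get(m[-1]) if m.endswith(("_B", "_T", "_Q")) else None
            res = assoc.test_gene(y, expression=e_pred, prs=p_vec, method=m)
            if res.p_value <= alpha:
                rejections[m] += 1
    return {m: rejections[m] / n_replicates for m in methods}


def run_type1(grid: ExperimentGrid,
              genes: tuple[GeneConfig, ...] = DEFAULT_GENES) -> CalibrationTable:
    """Empirical type-I error of every method over the (N, gene) grid.

    beta is forced to 0; each rate is flagged against the 95% binomial CI
    around the nominal level.
    """
    ci = ci_bounds(grid.alpha, grid.n_replicates)
    rows = []
    for gene in genes:
        pool, weights = _gene_pool_and_weights(gene, grid.seed)
        for N in grid.N_list:
            for prop in grid.prop_list:
                t0 = time.time()
                ss = _cell_seedseq(grid.seed, gene, N, 0.0, prop, grid.trait_type)
                try:
                    rates = run_cell(pool, weights, gene, beta=0.0, prop=prop,
                                     n=grid.n, N=N, trait_type=grid.trait_type,
                                     alpha=grid.alpha,
                                     n_replicates=grid.n_replicates,
                                     methods=grid.methods, seedseq=ss)
                except Exception as exc:   # abort the cell, keep the table
                    logger.error("cell (gene=%s, N=%d, prop=%g) failed: %s",
                                 gene.name, N, prop, exc)
                    continue
                logger.info("type-I cell gene=%s N=%d done in %.1fs",
                            gene.name, N, time.time() - t0)
                for m, rate in rates.items():
                    rows.append({"N": N, "gene": gene.name, "prop": prop,
                                 "method": m, "rate": rate,
                                 "ci_lower": ci[0], "ci_upper": ci[1],
                                 "within_ci": ci[0] <= rate <= ci[1]})
    return CalibrationTable(table=pd.DataFrame(rows), ci=ci)


def run_power(grid: ExperimentGrid,
              genes: tuple[GeneConfig, ...] = DEFAULT_GENES) -> pd.DataFrame:
    """Empirical power over the (beta, N, prop, gene) grid."""
    if not any(b > 0 for b in grid.betas):
        logger.warning("power grid contains no beta > 0")
    rows = []
    for gene in genes:
        pool, weights = _gene_pool_and_weights(gene, grid.seed)
        for N in grid.N_list:
            for prop in grid.prop_list:
                for beta in grid.betas:
                    ss = _cell_seedseq(grid.seed, gene, N, beta, prop,
                                       grid.trait_type)
                    rates = run_cell(pool, weights, gene, beta=beta, prop=prop,
                                     n=grid.n, N=N, trait_type=grid.trait_type,
                                     alpha=grid.alpha,
                                     n_replicates=grid.n_replicates,
                                     methods=grid.methods, seedseq=ss)
                    for m, rate in rates.items():
                        rows.append({"gene": gene.name, "scheme":
                                     gene.expression_scheme, "beta": beta,
                                     "N": N, "prop": prop, "method": m,
                                     "power": rate})
    return pd.DataFrame(rows)


def bonferroni_screen(p_values: dict[str, float] | pd.Series,
                      family_alpha: float = 0.05
                      ) -> tuple[list[str], float]:
    """Family-wise gene screening at ``family_alpha / n_genes``.

    Returns the significant gene list and the threshold rounded to 4
    significant digits (selection uses the unrounded threshold).
    """
    series = pd.Series(p_values, dtype=float)
    if series.empty:
        raise ValueError("need at least one gene")
    threshold = family_alpha / len(series)
    hits = list(series.index[series <= threshold])
    rounded = float(f"{threshold:.4g}")
    return hits, rounded


def plot_power_curves(power: pd.DataFrame, path: str, by: str = "gene") -> None:
    """One power-vs-beta panel per gene, one line per method (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(power.groupby(by))
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3.2),
                             squeeze=False, sharey=True)
    for ax, (key, sub) in zip(axes[0], groups):
        for method, line in sub.groupby("method"):
            line = line.sort_values("beta")
            ax.plot(line["beta"], line["power"], marker="o", label=method)
        ax.set_title(str(key))
        ax.set_xlabel("total effect beta")
        ax.set_ylim(0, 1)
    axes[0][0].set_ylabel("empirical power")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = ["GeneConfig", "ExperimentGrid", "CalibrationTable", "DEFAULT_GENES",
           "ci_bounds", "run_cell", "run_type1", "run_power",
           "bonferroni_screen", "plot_power_curves"]
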