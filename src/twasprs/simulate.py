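"""Synthetic genotypes, expression, and phenotypes for the simulation study.

The generator emulates resampling from a phased reference panel: a pool of
haplotypes with blockwise LD is synthesized once per gene (a Gaussian-copula
stand-in for real phased haplotypes, which are not distributable), and each
simulated individual is the sum of two haplotypes drawn uniformly with
replacement from the pool.

Expression is generated as ``E_i = W^T x_i + e_i`` with
``e_i ~ N(0, W^T Cov(X) W)``, so the genetic component explains about half
of the expression variance.  Phenotypes follow

    y_i = beta * (a E_i + sum_{j in causal} x_ij) + eps_i,  eps_i ~ N(0, 1)

where the causal set contains ``c = ceil(M * prop)`` SNPs drawn at random,
``a`` weighs the expression-mediated path against the direct genetic path
(default 1), and ``beta`` is the total effect (0 under the null).  Binary
traits are obtained by the liability threshold "mean + 1 SD", giving a
population prevalence of 1 - Phi(1) ~ 16%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import GenotypeMatrix, PhenotypeVector
from .expression import ExpressionWeights

DEFAULT_N_HAP = 10860       # 2 x 5430 phased individuals in the reference panel
DEFAULT_MAF_RANGE = (0.05, 0.5)
DEFAULT_BLOCK_LEN = 5
DEFAULT_BLOCK_RHO = 0.5


@dataclass
class HaplotypePool:
    """Pool of binary haplotypes (rows) over a gene's M SNPs (columns)."""

    H: np.ndarray
    snp_ids: list[str]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H)
        if self.H.ndim != 2:
            raise ValueError("haplotypes must be a 2-D array")
        if not np.isin(self.H, [0, 1]).all():
            raise ValueError("haplotype entries must be 0/1")
        if len(self.snp_ids) != self.H.shape[1]:
            raise ValueError("snp_ids length does not match haplotype columns")

    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[0]

    @property
    def n_snps(self) -> int:
        return self.H.shape[1]

    def allele_freq(self) -> np.ndarray:
        return self.H.mean(axis=0)


@dataclass
class SimConfig:
    """One simulation setting of the phenotype model."""

    beta: float = 0.0
    a: float = 1.0
    prop: float = 0.2
    n: int = 5000
    N: int = 5000
    trait_type: str = "quantitative"
    expression_scheme: str = "max"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prop <= 1.0):
            raise ValueError("prop must lie in (0, 1]")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError("trait_type must be quantitative or binary")
        if self.expression_scheme not in ("full", "max", "h"):
            raise ValueError("expression_scheme must be full, max, or h")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_blocks(M: int, block_len: int = DEFAULT_BLOCK_LEN,
                   rho: float = DEFAULT_BLOCK_RHO) -> list[tuple[int, float]]:
    """Tile M SNPs into LD blocks of ``block_len`` (remainder in the last)."""
    blocks = [(block_len, rho)] * (M // block_len)
    if M % block_len:
        blocks.append((M % block_len, rho))
    return blocks


def synthesize_haplotypes(M: int, block_structure: list[tuple[int, float]] | None = None,
                          maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
                          n_hap: int = DEFAULT_N_HAP, seed=0,
                          snp_ids: list[str] | None = None) -> HaplotypePool:
    """Blockwise-LD binary haplotypes via a thresholded Gaussian copula.

    Within each block a latent MVN with exchangeable correlation ``rho`` is
    thresholded at the quantile of each SNP's minor allele frequency (drawn
    uniformly from ``maf_range``), producing correlated 0/1 alleles whose
    allelic r^2 increases with rho; blocks are mutually independent.
    """
    if block_structure is None:
        block_structure = default_blocks(M)
    lengths = [b[0] for b in block_structure]
    if sum(lengths) != M or any(l < 1 for l in lengths):
        raise ValueError(f"block lengths {lengths} do not tile M={M}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = _rng(seed)
    mafs = rng.uniform(lo, hi, size=M)
    cols = []
    for length, rho in block_structure:
        if not (0.0 <= rho < 1.0):
            raise ValueError(f"within-block rho must lie in [0, 1), got {rho}")
        cov = np.full((length, length), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(length), cov, size=n_hap,
                                    method="cholesky")
        cols.append(z)
    z = np.concatenate(cols, axis=1)
    thresholds = stats.norm.ppf(mafs)
    H = (z < thresholds).astype(np.uint8)
    ids = snp_ids if snp_ids is not None else [f"snp{j + 1}" for j in range(M)]
    return HaplotypePool(H=H, snp_ids=list(ids))


def resample_genotypes(pool: HaplotypePool, n: int, seed=0) -> GenotypeMatrix:
    """Each individual is the sum of two haplotypes drawn with replacement."""
    if pool.n_haplotypes < 1:
        raise ValueError("empty haplotype pool")
    rng = _rng(seed)
    idx = rng.integers(0, pool.n_haplotypes, size=(2, n))
    dosages = (pool.H[idx[0]] + pool.H[idx[1]]).astype(float)
    samples = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, snp_ids=list(pool.snp_ids),
                          sample_ids=samples)


def sparsify_weights(W: ExpressionWeights, scheme: str) -> ExpressionWeights:
    """Restrict expression weights to the top eQTLs.

    ``full`` keeps W unchanged; ``max`` zeroes all but the single
    largest-magnitude entry; ``h`` keeps the two largest-magnitude entries.
    Ties break toward the lowest SNP index.
    """
    if scheme not in ("full", "max", "h"):
        raise ValueError("scheme must be full, max, or h")
    if scheme == "full":
        return ExpressionWeights(snp_ids=list(W.snp_ids), W=W.W.copy(),
                                 meta=dict(W.meta, scheme="full"))
    m = len(W.snp_ids)
    if scheme == "h" and m < 2:
        raise ValueError("scheme 'h' needs at least 2 SNPs")
    k = 1 if scheme == "max" else 2
    # stable argsort on -|W| breaks ties toward the lowest index
    order = np.argsort(-np.abs(W.W), kind="stable")
    out = np.zeros(m)
    out[order[:k]] = W.W[order[:k]]
    return ExpressionWeights(snp_ids=list(W.snp_ids), W=out,
                             meta=dict(W.meta, scheme=scheme))


def make_expression(geno: GenotypeMatrix, W: ExpressionWeights, seed=0) -> np.ndarray:
    """True expression ``E_i = W^T x_i + e_i`` with ``var(e) = W^T Cov(X) W``.

    The noise variance equals the genetic variance of expression computed
    from the sample covariance of the generated genotypes, so roughly half
    of the expression variance is genetic.
    """
    if W.snp_ids != geno.snp_ids:
        raise ValueError("weights not aligned with genotype columns")
    x = geno.dosages
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    sigma2 = float(W.W @ cov @ W.W)
    if sigma2 <= 0:
        raise ValueError("W^T Cov(X) W is zero — all weight on monomorphic "
                         "SNPs (or W = 0)")
    rng = _rng(seed)
    return x @ W.W + rng.normal(0.0, math.sqrt(sigma2), size=x.shape[0])


def select_causal(M: int, prop: float, seed=0) -> np.ndarray:
    """Draw ``c = ceil(M * prop)`` causal SNP indices without replacement."""
    if not (0.0 < prop <= 1.0):
        raise ValueError("prop must lie in (0, 1]")
    c = math.ceil(M * prop)
    rng = _rng(seed)
    return np.sort(rng.choice(M, size=c, replace=False))


def make_phenotype(E: np.ndarray, geno: GenotypeMatrix, causal: np.ndarray,
                   beta: float, a: float = 1.0, seed=0) -> PhenotypeVector:
    """Quantitative phenotype ``y = beta (a E + sum_causal x) + N(0, 1)``."""
    E = np.asarray(E, dtype=float).ravel()
    causal = np.asarray(causal, dtype=int)
    if causal.size and (causal.min() < 0 or causal.max() >= geno.n_snps):
        raise ValueError("causal indices outside the gene")
    rng = _rng(seed)
    direct = geno.dosages[:, causal].sum(axis=1) if causal.size else 0.0
    y = beta * (a * E + direct) + rng.normal(0.0, 1.0, size=E.shape[0])
    return PhenotypeVector(y, "quantitative")


def dichotomize(y: PhenotypeVector) -> PhenotypeVector:
    """Liability-threshold binary trait: case iff y >= mean + 1 sample SD.

    On a normal liability the case fraction is 1 - Phi(1) ~ 0.159, i.e. a
    population prevalence of about 16%.
    """
    y = np.asarray(y.y if isinstance(y, PhenotypeVector) else y, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    threshold = y.mean() + y.std(ddof=1)
    labels = (y >= threshold).astype(float)
    if labels.min() == labels.max():
        raise ValueError("dichotomization produced a single class; redraw")
    return PhenotypeVector(labels, "binary")


def draw_expression_weights(M: int, seed=0, scale: float = 0.5,
                            nonzero_frac: float = 0.2,
                            snp_ids: list[str] | None = None) -> ExpressionWeights:
    """Synthetic per-gene cis-effect vector emulating elastic-net eQTL weights.

    Elastic-net weight files are sparse: only a minority of a gene's SNPs
    carry a nonzero cis-effect.  ``max(2, ceil(M * nonzero_frac))`` SNPs are
    chosen at random and given effects ``W_m ~ N(0, scale^2)``; the rest are
    zero.  Stands in for pre-computed eQTL weight files in simulations;
    drawn once per gene and held fixed across replicates.
    """
    rng = _rng(seed)
    ids = snp_ids if snp_ids is not None else [f"snp{j + 1}" for j in range(M)]
    k = min(M, max(2, math.ceil(M * nonzero_frac)))
    support = rng.choice(M, size=k, replace=False)
    w = np.zeros(M)
    w[support] = rng.normal(0.0, scale, size=k)
    return ExpressionWeights(snp_ids=list(ids), W=w,
                             meta={"source": "synthetic", "scale": scale,
                                   "nonzero": int(k)})


__all__ = ["HaplotypePool", "SimConfig", "default_blocks",
           "synthesize_haplotypes", "resample_genotypes", "sparsify_weights",
           "make_expression", "select_causal", "make_phenotype",
           "dichotomize", "draw_expression_weights",
           "DEFAULT_N_HAP", "DEFAULT_MAF_RANGE"]
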