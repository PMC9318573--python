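"""Polygenic risk scores from GWAS summary statistics, with LD adjustment.

Three per-SNP weightings are supported for the PRS ``PRS_i = w^T x~_i``:

* ``B`` — the marginal effect estimate, ``w_m = beta_hat_m`` (the standard
  PRS weighting);
* ``T`` — the per-SNP score statistic, ``w_m = T_m``;
* ``Q`` — the signed squared score statistic, ``w_m = sign(T_m) T_m^2``,
  which up-weights strongly associated SNPs while keeping the direction of
  effect.

Linkage disequilibrium between the SNPs of a gene inflates the contribution
of correlated markers to a naive weighted sum.  Instead of LD pruning, the
genotypes are whitened with a truncated inverse square root of the sample
correlation matrix R: writing the eigendecomposition R = sum_l lambda_l
e_l e_l^T (eigenvalues descending), the transform keeps the smallest leading
set of L components whose eigenvalues cover at least ``cum_threshold``
(default 99.9%) of the total variance and uses

    R^(-1/2) ~= sum_{l<=L} e_l e_l^T / sqrt(lambda_l).

Truncation keeps the transform stable when R is near-singular, as it
typically is for SNPs in strong LD.  The PRS is then ``w^T R^(-1/2) x_i``
computed on column-standardized genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import GenotypeMatrix

SCHEMES = ("B", "T", "Q")


@dataclass
class GwasSummary:
    """Per-SNP marginal GWAS results for the SNPs of one gene.

    ``beta_hat`` are marginal effect estimates (phenotype units per effect
    allele), ``t_stat`` the corresponding score/Z statistics, and
    ``p_value`` two-sided p-values.  ``t_stat`` entries may be NaN when only
    (p, sign of beta) is available; they are then recovered with
    :func:`t_from_pvalue` on demand.
    """

    snp_ids: list[str]
    beta_hat: np.ndarray
    t_stat: np.ndarray | None = None
    p_value: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        m = len(self.snp_ids)
        if m < 1:
            raise ValueError("summary must cover at least one SNP")
        self.beta_hat = np.asarray(self.beta_hat, dtype=float).ravel()
        if self.beta_hat.shape[0] != m:
            raise ValueError("beta_hat length does not match snp_ids")
        if self.t_stat is not None:
            self.t_stat = np.asarray(self.t_stat, dtype=float).ravel()
            if self.t_stat.shape[0] != m:
                raise ValueError("t_stat length does not match snp_ids")
        if self.p_value is not None:
            self.p_value = np.asarray(self.p_value, dtype=float).ravel()
            if self.p_value.shape[0] != m:
                raise ValueError("p_value length does not match snp_ids")
            if np.any(self.p_value <= 0) or np.any(self.p_value > 1):
                raise ValueError("p-values must lie in (0, 1]")
        if self.t_stat is None and self.p_value is None:
            raise ValueError("need t_stat or p_value")
        self._validate_consistency()

    def _validate_consistency(self) -> None:
        if self.t_stat is not None:
            ok = np.isfinite(self.t_stat)
            # direction must agree with beta_hat where both are nonzero
            t, b = self.t_stat[ok], self.beta_hat[ok]
            both = (np.abs(t) > 1e-12) & (np.abs(b) > 1e-12)
            if np.any(np.sign(t[both]) != np.sign(b[both])):
                raise ValueError("sign(t_stat) disagrees with sign(beta_hat)")
            if self.p_value is not None:
                p_implied = 2.0 * stats.norm.sf(np.abs(t))
                if np.any(np.abs(self.p_value[ok] - p_implied) > 1e-6):
                    raise ValueError("p_value inconsistent with t_stat "
                                     "(expected p = 2(1 - Phi(|T|)))")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def scores(self) -> np.ndarray:
        """Score statistics, filling missing entries from (p, sign(beta))."""
        if self.t_stat is not None and np.isfinite(self.t_stat).all():
            return self.t_stat.copy()
        t = np.full(self.n_snps, np.nan) if self.t_stat is None else self.t_stat.copy()
        need = ~np.isfinite(t)
        if self.p_value is None:
            bad = [self.snp_ids[i] for i in np.flatnonzero(need)]
            raise ValueError(f"no t_stat and no p_value for SNPs {bad}")
        for i in np.flatnonzero(need):
            if not np.isfinite(self.p_value[i]):
                raise ValueError(f"SNP {self.snp_ids[i]}: neither t_stat nor "
                                 "p_value available")
            sign = 1.0 if self.beta_hat[i] >= 0 else -1.0
            t[i] = t_from_pvalue(self.p_value[i], sign)
        return t

    def subset(self, keep: list[str]) -> "GwasSummary":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        idx = [index[s] for s in keep]
        return GwasSummary(
            snp_ids=keep,
            beta_hat=self.beta_hat[idx],
            t_stat=None if self.t_stat is None else self.t_stat[idx],
            p_value=None if self.p_value is None else self.p_value[idx],
        )


@dataclass
class PrsWeights:
    """Per-SNP PRS weight vector under one of the B/T/Q schemes."""

    scheme: str
    snp_ids: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        self.w = np.asarray(self.w, dtype=float).ravel()
        if len(self.snp_ids) != self.w.shape[0]:
            raise ValueError("weight length does not match snp_ids")


@dataclass
class LdTransform:
    """Eigendecomposition of a gene's LD matrix and its truncated R^(-1/2)."""

    correlation: np.ndarray
    eigenvalues: np.ndarray          # descending
    eigenvectors: np.ndarray         # orthonormal columns, matching order
    retained: int                    # L
    inv_sqrt: np.ndarray
    cum_threshold: float = 0.999
    snp_ids: list[str] | None = None

    @property
    def n_snps(self) -> int:
        return self.correlation.shape[0]


def t_from_pvalue(p: float, effect_sign: float) -> float:
    """Recover the signed score statistic from a two-sided p-value.

    Inverts p = 2(1 - Phi(|T|)): returns ``effect_sign * Phi^-1(1 - p/2)``.
    ``p = 1`` maps to 0 regardless of the sign.
    """
    p = float(p)
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value must lie in (0, 1], got {p}")
    if effect_sign not in (-1, 1, -1.0, 1.0):
        raise ValueError("effect_sign must be +1 or -1")
    return float(effect_sign) * float(stats.norm.isf(p / 2.0))


def build_weights(summary: GwasSummary, scheme: str) -> PrsWeights:
    """Construct B/T/Q PRS weights from GWAS summary statistics."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if scheme == "B":
        w = summary.beta_hat.copy()
    else:
        t = summary.scores()
        w = t if scheme == "T" else np.sign(t) * t ** 2
    return PrsWeights(scheme=scheme, snp_ids=list(summary.snp_ids), w=w)


def _dosage_array(geno) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(geno, GenotypeMatrix):
        return geno.dosages, geno.snp_ids
    x = np.asarray(geno, dtype=float)
    if x.ndim != 2:
        raise ValueError("genotypes must be 2-D (samples x SNPs)")
    return x, None


def sample_correlation(geno) -> np.ndarray:
    """Sample correlation matrix R of the gene's genotype columns.

    Raises if any column has zero variance — monomorphic SNPs must be
    dropped first (see :meth:`GenotypeMatrix.drop_monomorphic`).
    """
    x, ids = _dosage_array(geno)
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples to estimate correlation")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        names = [ids[i] for i in bad] if ids else list(bad)
        raise ValueError(f"zero-variance SNP columns: {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(np.asarray(r, dtype=float))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def ld_inverse_sqrt(R: np.ndarray, cum_threshold: float = 0.999,
                    snp_ids: list[str] | None = None) -> LdTransform:
    """Truncated inverse square root of a correlation matrix.

    Keeps the smallest number L of leading eigenpairs whose eigenvalues sum
    to at least ``cum_threshold`` of the trace, then forms
    ``sum_{l<=L} e_l e_l^T / sqrt(lambda_l)``.  Eigenvalues in
    [-1e-8, 0) are treated as floating-point zeros; anything more negative
    is an error.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if np.max(np.abs(R - R.T)) > 1e-8:
        raise ValueError("R is not symmetric")
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    if np.any(vals < -1e-8):
        raise ValueError(f"R has negative eigenvalue {vals.min():.3e}")
    vals = np.clip(vals, 0.0, None)
    cum = np.cumsum(vals)
    total = cum[-1]
    if total <= 0:
        raise ValueError("R has zero trace after clipping")
    L = int(np.argmax(cum / total >= cum_threshold)) + 1
    # a zero eigenvalue can never be the one that tips the cumulative sum
    while L > 0 and vals[L - 1] <= 0.0:
        L -= 1
    lead_vecs = vecs[:, :L]
    inv_sqrt = (lead_vecs / np.sqrt(vals[:L])) @ lead_vecs.T
    inv_sqrt = (inv_sqrt + inv_sqrt.T) / 2.0
    return LdTransform(correlation=R, eigenvalues=vals, eigenvectors=vecs,
                       retained=L, inv_sqrt=inv_sqrt,
                       cum_threshold=cum_threshold, snp_ids=snp_ids)


def adjust_genotypes(geno, transform: LdTransform) -> np.ndarray:
    """LD-adjusted genotypes ``x~_i = R^(-1/2) z_i``.

    Genotype columns are standardized (mean 0, unit variance) before the
    whitening transform, since R is a correlation matrix and the inverse
    square root only decorrelates standardized scores.
    """
    x, ids = _dosage_array(geno)
    if x.shape[1] != transform.n_snps:
        raise ValueError(f"genotypes have {x.shape[1]} SNPs but transform "
                         f"was built for {transform.n_snps}")
    if ids is not None and transform.snp_ids is not None and ids != transform.snp_ids:
        raise ValueError("SNP order differs between genotypes and transform")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("cannot standardize zero-variance columns")
    z = (x - mu) / sd
    return z @ transform.inv_sqrt       # inv_sqrt is symmetric


def compute_prs(adjusted: np.ndarray, weights) -> np.ndarray:
    """Per-individual PRS: ``PRS_i = sum_m w_m x~_im``."""
    w = weights.w if isinstance(weights, PrsWeights) else np.asarray(weights, dtype=float)
    adjusted = np.asarray(adjusted, dtype=float)
    if adjusted.shape[1] != w.shape[0]:
        raise ValueError(f"{w.shape[0]} weights for {adjusted.shape[1]} SNP columns")
    return adjusted @ w


__all__ = ["GwasSummary", "PrsWeights", "LdTransform", "SCHEMES",
           "t_from_pvalue", "build_weights", "sample_correlation",
           "ld_inverse_sqrt", "adjust_genotypes", "compute_prs"]
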