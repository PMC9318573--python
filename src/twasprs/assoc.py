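"""Gene-level score tests and per-SNP GWAS summary generation.

The association model is a generalized linear model relating the phenotype
to genetically predicted expression E and/or an LD-adjusted PRS:

    quantitative:  y_i = b0 + b1 E_i + b2 PRS_i + eps_i
    binary:        logit P(y_i = 1) = b0 + b1 E_i + b2 PRS_i

Gene-level hypotheses are tested with the efficient score test evaluated at
the intercept-only null fit: the joint test of H0: b1 = b2 = 0 is chi^2
with 2 df, and the single-predictor variants (TWAS on E alone, PRS_B/T/Q on
the PRS alone) are chi^2 with 1 df.  Covariates are handled by regressing
them out of the phenotype first and testing the residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GenotypeMatrix, PhenotypeVector, as_phenotype
from .expression import PredictedExpression
from .prs import GwasSummary

logger = logging.getLogger(__name__)

METHODS = ("TWAS", "PRS_B", "PRS_T", "PRS_Q",
           "TWAS-PRS_B", "TWAS-PRS_T", "TWAS-PRS_Q")


@dataclass
class ScoreTestResult:
    """Chi-squared score test for one gene under one method."""

    statistic: float
    df: int
    p_value: float
    method: str | None = None

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-squared statistic must be non-negative")


def residualize(y: PhenotypeVector, covariates: np.ndarray) -> PhenotypeVector:
    """Regress the phenotype on [1, covariates]; return the residuals.

    The residuals are treated as a quantitative trait downstream (this is
    how binary phenotypes with covariates are handled too).  Raises on
    rank-deficient covariates, naming the collinear columns.
    """
    y = as_phenotype(y)
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != y.n:
        c = c.T
    if c.shape[0] != y.n:
        raise ValueError("covariate rows do not match phenotype length")
    design = np.column_stack([np.ones(y.n), c])
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    dead = np.flatnonzero(diag < tol)
    if dead.size:
        names = [("intercept" if j == 0 else f"covariate_{j - 1}") for j in dead]
        raise ValueError(f"covariate matrix is rank deficient; collinear "
                         f"columns: {names}")
    coef, *_ = np.linalg.lstsq(design, y.y, rcond=None)
    resid = y.y - design @ coef
    return PhenotypeVector(resid, "quantitative")


def score_test(y: PhenotypeVector, predictors: np.ndarray,
               method: str | None = None) -> ScoreTestResult:
    """Efficient score test of H0: all predictor coefficients are zero.

    Under the intercept-only null fit with mean mu = y-bar, the score is
    U = Z~^T (y - mu) with Z~ the column-centered predictor matrix, and the
    null information is V = phi * Z~^T Z~ where phi is sigma-hat^2 =
    sum (y - y-bar)^2 / n for a quantitative trait and y-bar (1 - y-bar)
    for a binary one.  The statistic U^T V^-1 U is chi^2 with df = number
    of predictors; if V is numerically singular (collinear predictors) an
    eigenvalue-thresholded pseudo-inverse is used and df drops to the
    numerical rank.
    """
    y = as_phenotype(y)
    z = np.asarray(predictors, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n, q = z.shape
    if n != y.n:
        raise ValueError("predictor rows do not match phenotype length")
    if n <= q + 1:
        raise ValueError(f"need n > q + 1 (n={n}, q={q})")
    if np.any(z.std(axis=0) == 0):
        raise ValueError("zero-variance predictor column")
    yc = y.y - y.y.mean()
    if y.trait_type == "quantitative":
        phi = float(yc @ yc) / n
        if phi == 0:
            raise ValueError("phenotype has zero variance")
    else:
        mu = float(y.y.mean())
        phi = mu * (1.0 - mu)
    zc = z - z.mean(axis=0)
    u = zc.T @ yc
    v = phi * (zc.T @ zc)
    vals, vecs = np.linalg.eigh(v)
    lam_max = vals.max()
    keep = vals > 1e-10 * lam_max
    if keep.sum() < q:
        logger.warning("singular score information (rank %d < %d); using "
                       "generalized inverse", int(keep.sum()), q)
    proj = vecs[:, keep].T @ u
    statistic = float(np.sum(proj ** 2 / vals[keep]))
    statistic = max(statistic, 0.0)
    df = int(keep.sum())
    p = float(stats.chi2.sf(statistic, df))
    return ScoreTestResult(statistic=statistic, df=df,
                           p_value=max(p, np.finfo(float).tiny), method=method)


def test_gene(y: PhenotypeVector, expression=None, prs=None,
              method: str = "TWAS-PRS_Q") -> ScoreTestResult:
    """Dispatch one of the seven gene-level tests.

    ``TWAS`` tests predicted expression alone (1 df); ``PRS_B/T/Q`` test the
    corresponding PRS alone (1 df); ``TWAS-PRS_B/T/Q`` jointly test
    expression and PRS (2 df).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    e = expression.E if isinstance(expression, PredictedExpression) else expression
    cols = []
    if method.startswith("TWAS"):
        if e is None:
            raise ValueError(f"method {method} requires predicted expression")
        cols.append(np.asarray(e, dtype=float))
    if "PRS" in method:
        if prs is None:
            raise ValueError(f"method {method} requires a PRS vector")
        cols.append(np.asarray(prs, dtype=float))
    return score_test(y, np.column_stack(cols), method=method)


def _logistic_slopes(y: np.ndarray, x: np.ndarray, max_iter: int = 50,
                     tol: float = 1e-8) -> np.ndarray:
    """Per-SNP logistic MLE slopes, Newton iterations vectorized across SNPs."""
    n, m = x.shape
    b0 = np.full(m, np.log(y.mean() / (1 - y.mean())))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        eta = b0 + x * b1
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = y[:, None] - p
        g0, g1 = r.sum(axis=0), (x * r).sum(axis=0)
        i00 = w.sum(axis=0)
        i01 = (w * x).sum(axis=0)
        i11 = (w * x * x).sum(axis=0)
        det = i00 * i11 - i01 ** 2
        d0 = (i11 * g0 - i01 * g1) / det
        d1 = (i00 * g1 - i01 * g0) / det
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(), np.abs(d1).max()) < tol:
            break
    return b1


def per_snp_summary(y: PhenotypeVector, geno: GenotypeMatrix) -> GwasSummary:
    """Marginal single-SNP GWAS over the gene: beta-hat, score statistic, p.

    For each polymorphic SNP m the marginal model ``y ~ x_m`` gives the OLS
    slope (quantitative) or logistic MLE slope (binary) as beta-hat_m; the
    signed square root of the 1-df score statistic is T_m and
    ``p_m = 2 (1 - Phi(|T_m|))``.  Monomorphic SNPs are excluded with a
    warning.
    """
    y = as_phenotype(y)
    geno = geno.drop_monomorphic()
    x = geno.dosages
    n = x.shape[0]
    if n != y.n:
        raise ValueError("phenotype length does not match genotype rows")
    if n < 30:
        logger.warning("per-SNP summary on only n=%d samples", n)
    xc = x - x.mean(axis=0)
    yc = y.y - y.y.mean()
    sxx = (xc ** 2).sum(axis=0)
    u = xc.T @ yc
    if y.trait_type == "quantitative":
        beta = u / sxx
        phi = float(yc @ yc) / n
    else:
        beta = _logistic_slopes(y.y, x)
        mu = float(y.y.mean())
        phi = mu * (1.0 - mu)
    t = u / np.sqrt(phi * sxx)
    # MLE slope sign can wobble at |T| ~ 0; keep signs consistent
    flip = (np.sign(beta) != np.sign(t)) & (np.abs(t) > 1e-12)
    if flip.any():
        beta = beta.copy()
        beta[flip] = np.abs(beta[flip]) * np.sign(t[flip])
    p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return GwasSummary(snp_ids=list(geno.snp_ids), beta_hat=beta,
                       t_stat=t, p_value=p)


__all__ = ["METHODS", "ScoreTestResult", "residualize", "score_test",
           "test_gene", "per_snp_summary"]
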