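"""Cis-eQTL expression weights and genetically predicted expression.

Gene expression is modelled as a linear function of the gene's SNP dosages,
``ge_i = sum_m W_m x_im + noise``; the cis-effect vector W is estimated by
elastic net on an eQTL training panel and then used to *predict* expression
in the association sample as ``E_i = W^T x_i`` (no intercept — constants
are absorbed by the association model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .data import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ExpressionWeights:
    """Per-SNP cis-effects of a gene (expression units per effect allele)."""

    snp_ids: list[str]
    W: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.W = np.asarray(self.W, dtype=float).ravel()
        if self.W.shape[0] != len(self.snp_ids):
            raise ValueError("weight length does not match snp_ids")
        if not np.isfinite(self.W).all():
            raise ValueError("weights must be finite")


@dataclass
class PredictedExpression:
    """Per-individual predicted expression ``E_i = W^T x_i``."""

    E: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float).ravel()


def fit_expression_weights(eqtl_geno: GenotypeMatrix, expr,
                           l1_ratio: float = 0.5, n_folds: int = 5,
                           seed: int = 0, alpha: float | None = None,
                           n_alphas: int = 50) -> ExpressionWeights:
    """Elastic-net fit of cis-eQTL weights on an eQTL training panel.

    Genotypes are standardized internally; the returned weights are
    back-transformed to the per-allele scale so that prediction uses raw
    dosages.  The penalty strength is chosen by ``n_folds``-fold
    cross-validation minimizing MSE (fold assignment seeded for
    reproducibility) unless ``alpha`` is given explicitly.

    Parameters
    ----------
    l1_ratio : elastic-net mixing (1 = lasso, 0 = ridge); default 0.5.
    alpha : optional fixed penalty, bypassing cross-validation.
    """
    y = np.asarray(expr, dtype=float).ravel()
    x = eqtl_geno.dosages
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("expression vector not aligned with samples")
    if y.std() == 0:
        raise ValueError("expression has zero variance")
    if n < n_folds:
        raise ValueError(f"training n={n} smaller than n_folds={n_folds}")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"monomorphic SNPs in training genotypes: "
                         f"{eqtl_geno.monomorphic_ids()}; drop them first")
    z = (x - x.mean(axis=0)) / sd
    if alpha is not None:
        model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=10000)
        model.fit(z, y)
        chosen_alpha = float(alpha)
    else:
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        model = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, alphas=n_alphas,
                             max_iter=10000)
        model.fit(z, y)
        chosen_alpha = float(model.alpha_)
    w = model.coef_ / sd                     # back to per-allele scale
    return ExpressionWeights(
        snp_ids=list(eqtl_geno.snp_ids), W=w,
        meta={"alpha": chosen_alpha, "l1_ratio": l1_ratio, "n_train": n,
              "n_folds": None if alpha is not None else n_folds},
    )


def predict_expression(geno: GenotypeMatrix, weights: ExpressionWeights,
                       missing: str = "strict") -> PredictedExpression:
    """Predict expression from raw dosages, ``E_i = sum_m W_m x_im``.

    SNPs are matched by identifier.  A weighted SNP absent from the
    genotypes raises (``missing='strict'``, default) or is dropped with a
    warning (``missing='lenient'``).  Allele harmonization is the loader's
    job (:func:`twasprs.io.align_gene`).
    """
    if missing not in ("strict", "lenient"):
        raise ValueError("missing must be 'strict' or 'lenient'")
    have = set(geno.snp_ids)
    absent = [s for s in weights.snp_ids if s not in have]
    if absent:
        if missing == "strict":
            raise KeyError(f"weighted SNPs absent from genotypes: {absent}")
        logger.warning("dropping %d weighted SNPs absent from genotypes: %s",
                       len(absent), absent)
    keep = [s for s in weights.snp_ids if s in have]
    if not keep:
        raise ValueError("no weighted SNP present in the genotypes")
    sub = geno.subset_snps(keep)
    index = {s: i for i, s in enumerate(weights.snp_ids)}
    w = weights.W[[index[s] for s in keep]]
    return PredictedExpression(E=sub.dosages @ w)


__all__ = ["ExpressionWeights", "PredictedExpression",
           "fit_expression_weights", "predict_expression"]
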