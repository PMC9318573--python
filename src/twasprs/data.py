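"""Core containers shared across the package.

A :class:`GenotypeMatrix` holds per-individual allele dosages for the M SNPs
of one gene, together with SNP/sample identifiers and (optionally) the
counted effect allele per SNP.  A :class:`PhenotypeVector` is a length-n
trait vector tagged as quantitative or binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """n x M dosage matrix with SNP metadata.

    Dosages count copies of the effect allele, so every entry lies in
    [0, 2].  Missing genotypes must be imputed (per-SNP mean) before
    construction; loaders in :mod:`twasprs.io` do this automatically.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    effect_alleles: list[str] | None = None
    other_alleles: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x SNPs) array")
        n, m = self.dosages.shape
        self.snp_ids = list(self.snp_ids)
        self.sample_ids = list(self.sample_ids)
        if len(self.snp_ids) != m:
            raise ValueError(f"{len(self.snp_ids)} snp_ids for {m} dosage columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} dosage rows")
        if np.isnan(self.dosages).any():
            raise ValueError("dosages contain missing values; impute at load time")
        if self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")
        for name in ("effect_alleles", "other_alleles"):
            val = getattr(self, name)
            if val is not None and len(val) != m:
                raise ValueError(f"{name} length does not match SNP count")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def monomorphic_mask(self) -> np.ndarray:
        """Boolean mask of columns with zero variance."""
        return self.dosages.std(axis=0) == 0.0

    def monomorphic_ids(self) -> list[str]:
        mask = self.monomorphic_mask()
        return [s for s, m in zip(self.snp_ids, mask) if m]

    def subset_snps(self, keep: np.ndarray | list[str]) -> "GenotypeMatrix":
        """Restrict (and reorder) to the given SNPs.

        ``keep`` is either a boolean/index array over columns or a list of
        SNP identifiers in the desired output order.
        """
        if isinstance(keep, (list, tuple)) and keep and isinstance(keep[0], str):
            index = {s: i for i, s in enumerate(self.snp_ids)}
            missing = [s for s in keep if s not in index]
            if missing:
                raise KeyError(f"SNPs absent from genotype matrix: {missing}")
            idx = np.array([index[s] for s in keep], dtype=int)
        else:
            idx = np.asarray(keep)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            sample_ids=self.sample_ids,
            effect_alleles=None if self.effect_alleles is None
            else [self.effect_alleles[i] for i in idx],
            other_alleles=None if self.other_alleles is None
            else [self.other_alleles[i] for i in idx],
        )

    def drop_monomorphic(self) -> "GenotypeMatrix":
        """Drop zero-variance SNPs, logging which ones were removed."""
        mask = self.monomorphic_mask()
        if mask.any():
            logger.warning("dropping %d monomorphic SNPs: %s",
                           mask.sum(), self.monomorphic_ids())
            return self.subset_snps(~mask)
        return self


@dataclass
class PhenotypeVector:
    """Length-n trait vector; binary traits are coded {0, 1}."""

    y: np.ndarray
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            values = np.unique(self.y)
            if not np.isin(values, [0.0, 1.0]).all():
                raise ValueError("binary trait must contain only 0/1")
            if len(values) < 2:
                raise ValueError("binary trait must contain both classes")

    @property
    def n(self) -> int:
        return self.y.shape[0]


def as_phenotype(y, trait_type: str = "quantitative") -> PhenotypeVector:
    """Coerce an array (or pass through a PhenotypeVector)."""
    if isinstance(y, PhenotypeVector):
        return y
    return PhenotypeVector(np.asarray(y, dtype=float), trait_type)


__all__ = ["GenotypeMatrix", "PhenotypeVector", "as_phenotype"]
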