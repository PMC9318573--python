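"""Readers/writers for genotype, summary-statistic, weight and result files,
plus SNP/allele harmonization across them.

Formats
-------
* Genotypes: VCF (dosage = count of ALT alleles from the GT field) or a TSV
  matrix ``sample_id x snp_id`` with values in [0, 2].  The TSV may carry a
  sidecar header line ``#counted_allele<TAB>A1<TAB>A2...`` declaring the
  counted (effect) allele per SNP column.
* GWAS summary statistics: TSV ``snp_id, effect_allele, beta, z, p``
  (``z`` may be empty when ``p`` plus the sign of ``beta`` is available).
* Expression weights: TSV ``gene_id, snp_id, effect_allele, weight``.
* PRS weights out: TSV ``snp_id, scheme, weight``.
* Gene-level results: TSV ``gene_id, method, statistic, df, p_value, n,
  M_snps``.

Missing genotypes are mean-imputed per SNP at load time (count logged).
All loaders check row-length consistency and fail loudly on truncated
files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import ScoreTestResult
from .data import GenotypeMatrix
from .expression import ExpressionWeights
from .prs import GwasSummary, PrsWeights

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- genotypes

def load_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from VCF or TSV (auto-detected by suffix)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if format == "vcf":
        return _load_vcf(path)
    if format == "tsv":
        return _load_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, eff, other = [], [], [], []
    n_imputed = 0
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("dropping multi-allelic site %s", var.ID or var.POS)
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        g = np.asarray(var.gt_types, dtype=float)
        dose = np.where(g == 3, 2.0, g)
        miss = g == 2
        if miss.any():
            known = dose[~miss]
            dose[miss] = known.mean() if known.size else 0.0
            n_imputed += int(miss.sum())
        cols.append(dose)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        eff.append(var.ALT[0])
        other.append(var.REF)
    if n_imputed:
        logger.info("mean-imputed %d missing genotype calls", n_imputed)
    if not cols:
        raise ValueError(f"no usable biallelic sites in {path}")
    return GenotypeMatrix(dosages=np.column_stack(cols), snp_ids=ids,
                          sample_ids=samples, effect_alleles=eff,
                          other_alleles=other)


def _load_genotype_tsv(path: Path) -> GenotypeMatrix:
    lines = Path(path).read_text().rstrip("\n").split("\n")
    alleles = None
    if lines and lines[0].startswith("#counted_allele"):
        alleles = lines[0].split("\t")[1:]
        lines = lines[1:]
    if not lines:
        raise ValueError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    if header[0] != "sample_id":
        raise ValueError(f"{path}: first header column must be 'sample_id'")
    snp_ids = header[1:]
    width = len(header)
    samples, rows, n_imputed = [], [], 0
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != width:
            raise ValueError(f"{path}:{lineno}: expected {width} fields, "
                             f"got {len(parts)} (truncated file?)")
        samples.append(parts[0])
        rows.append([np.nan if v in ("", "NA", ".") else float(v)
                     for v in parts[1:]])
    dosages = np.asarray(rows, dtype=float)
    if np.isnan(dosages).any():
        col_means = np.nanmean(dosages, axis=0)
        idx = np.where(np.isnan(dosages))
        n_imputed = idx[0].size
        dosages[idx] = np.take(col_means, idx[1])
        logger.info("mean-imputed %d missing genotype entries", n_imputed)
    if alleles is not None and len(alleles) != len(snp_ids):
        raise ValueError(f"{path}: counted_allele line does not match SNP count")
    return GenotypeMatrix(dosages=dosages, snp_ids=snp_ids,
                          sample_ids=samples, effect_alleles=alleles)


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        if geno.effect_alleles is not None:
            fh.write("#counted_allele\t" + "\t".join(geno.effect_alleles) + "\n")
        fh.write("sample_id\t" + "\t".join(geno.snp_ids) + "\n")
        for sample, row in zip(geno.sample_ids, geno.dosages):
            fh.write(sample + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


# ------------------------------------------------------- phenotype / tables

def load_phenotype(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV with columns ``sample_id`` and ``phenotype``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_phenotype(sample_ids, y, path: str | Path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "phenotype": np.asarray(y).ravel()}
                 ).to_csv(path, sep="\t", index=False)


def load_summary(path: str | Path) -> GwasSummary:
    """Summary-stat TSV ``snp_id, effect_allele, beta, z, p``."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "effect_allele", "beta"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    z = df["z"].to_numpy(float) if "z" in df.columns else None
    p = df["p"].to_numpy(float) if "p" in df.columns else None
    if z is None and p is None:
        raise ValueError(f"{path}: need a 'z' or a 'p' column")
    summary = GwasSummary(snp_ids=list(df["snp_id"].astype(str)),
                          beta_hat=df["beta"].to_numpy(float),
                          t_stat=z, p_value=p)
    summary.effect_alleles = list(df["effect_allele"].astype(str))
    return summary


def write_summary(summary: GwasSummary, path: str | Path,
                  effect_alleles: list[str] | None = None) -> None:
    alleles = effect_alleles or getattr(summary, "effect_alleles", None)
    df = pd.DataFrame({
        "snp_id": summary.snp_ids,
        "effect_allele": alleles if alleles is not None
        else ["."] * summary.n_snps,
        "beta": summary.beta_hat,
        "z": summary.t_stat if summary.t_stat is not None else summary.scores(),
        "p": summary.p_value,
    })
    df.to_csv(path, sep="\t", index=False)


def load_expression_weights(path: str | Path,
                            gene_id: str | None = None) -> ExpressionWeights:
    """Weight TSV ``gene_id, snp_id, effect_allele, weight`` (one gene)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "snp_id", "effect_allele", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if gene_id is not None:
        df = df[df["gene_id"] == gene_id]
        if df.empty:
            raise ValueError(f"{path}: no rows for gene {gene_id!r}")
    elif df["gene_id"].nunique() > 1:
        raise ValueError(f"{path}: multiple genes present; pass gene_id")
    w = ExpressionWeights(snp_ids=list(df["snp_id"].astype(str)),
                          W=df["weight"].to_numpy(float),
                          meta={"gene_id": str(df["gene_id"].iloc[0])})
    w.effect_alleles = list(df["effect_allele"].astype(str))
    return w


def write_expression_weights(weights: ExpressionWeights, gene_id: str,
                             path: str | Path,
                             effect_alleles: list[str] | None = None) -> None:
    alleles = effect_alleles or getattr(weights, "effect_alleles", None)
    pd.DataFrame({
        "gene_id": gene_id, "snp_id": weights.snp_ids,
        "effect_allele": alleles if alleles is not None
        else ["."] * len(weights.snp_ids),
        "weight": weights.W,
    }).to_csv(path, sep="\t", index=False)


def write_prs_weights(weights: PrsWeights, path: str | Path) -> None:
    pd.DataFrame({"snp_id": weights.snp_ids, "scheme": weights.scheme,
                  "weight": weights.w}).to_csv(path, sep="\t", index=False)


def write_results(results: list[ScoreTestResult], gene_id: str, n: int,
                  m_snps: int, path: str | Path) -> None:
    pd.DataFrame([{"gene_id": gene_id, "method": r.method,
                   "statistic": r.statistic, "df": r.df,
                   "p_value": r.p_value, "n": n, "M_snps": m_snps}
                  for r in results]).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- harmonization

@dataclass
class AlignedGeneData:
    """Genotypes, expression weights and GWAS summary on one SNP set.

    All three components share the same ``snp_ids`` sequence; allele
    mismatches that could be resolved by swapping the counted allele have
    had the weight/effect signs negated, everything else was dropped.  The
    ``report`` lists each action taken.
    """

    genotypes: GenotypeMatrix
    weights: ExpressionWeights
    summary: GwasSummary
    report: dict = field(default_factory=dict)


def _harmonize_signs(record_alleles, geno_eff, geno_other, snp_ids):
    """Return (keep_mask, sign_flips) for records vs the genotype alleles."""
    keep = np.ones(len(snp_ids), dtype=bool)
    sign = np.ones(len(snp_ids))
    flipped, dropped = [], []
    if record_alleles is None or geno_eff is None:
        return keep, sign, flipped, dropped
    for i, s in enumerate(snp_ids):
        rec, eff = record_alleles[i], geno_eff[i]
        if rec == eff or rec == "." or eff == ".":
            continue
        other = geno_other[i] if geno_other is not None else None
        if other is not None and rec == other:
            sign[i] = -1.0
            flipped.append(s)
        else:
            keep[i] = False
            dropped.append(s)
    return keep, sign, flipped, dropped


def align_gene(geno: GenotypeMatrix, weights: ExpressionWeights,
               summary: GwasSummary) -> AlignedGeneData:
    """Intersect the three SNP sets and harmonize effect alleles.

    Matching is by SNP identifier; a weight or summary record whose effect
    allele equals the genotype's *other* allele has its sign negated (the
    equivalent of mirroring the dosage), and an unresolvable allele
    mismatch drops the SNP.  Raises when the intersection is empty.
    """
    common = [s for s in geno.snp_ids
              if s in set(weights.snp_ids) and s in set(summary.snp_ids)]
    if not common:
        raise ValueError("no SNP shared by genotypes, weights and summary")
    g = geno.subset_snps(common)
    w_index = {s: i for i, s in enumerate(weights.snp_ids)}
    s_sub = summary.subset(common)
    w_alleles = getattr(weights, "effect_alleles", None)
    s_alleles = getattr(summary, "effect_alleles", None)
    w_all = ([w_alleles[w_index[s]] for s in common]
             if w_alleles is not None else None)
    s_index = {s: i for i, s in enumerate(summary.snp_ids)}
    s_all = ([s_alleles[s_index[s]] for s in common]
             if s_alleles is not None else None)

    keep_w, sign_w, flip_w, drop_w = _harmonize_signs(
        w_all, g.effect_alleles, g.other_alleles, common)
    keep_s, sign_s, flip_s, drop_s = _harmonize_signs(
        s_all, g.effect_alleles, g.other_alleles, common)
    keep = keep_w & keep_s
    if not keep.any():
        raise ValueError("no SNP left after allele harmonization")
    kept_ids = [s for s, k in zip(common, keep) if k]
    g = g.subset_snps(kept_ids)
    w_vec = np.array([weights.W[w_index[s]] for s in common]) * sign_w
    aligned_w = ExpressionWeights(snp_ids=kept_ids, W=w_vec[keep],
                                  meta=dict(weights.meta))
    s_kept = s_sub.subset(kept_ids)
    sign_keep = sign_s[keep]
    aligned_s = GwasSummary(
        snp_ids=kept_ids,
        beta_hat=s_kept.beta_hat * sign_keep,
        t_stat=None if s_kept.t_stat is None else s_kept.t_stat * sign_keep,
        p_value=s_kept.p_value)
    report = {
        "n_common": len(common), "n_kept": len(kept_ids),
        "weight_sign_flips": flip_w, "summary_sign_flips": flip_s,
        "dropped_allele_mismatch": sorted(set(drop_w) | set(drop_s)),
        "dropped_not_shared": [s for s in geno.snp_ids if s not in set(common)],
    }
    if report["dropped_allele_mismatch"]:
        logger.warning("dropped %d SNPs with unresolvable allele mismatch",
                       len(report["dropped_allele_mismatch"]))
    return AlignedGeneData(genotypes=g, weights=aligned_w, summary=aligned_s,
                           report=report)


def export_dataset(outdir: str | Path, geno: GenotypeMatrix, y,
                   weights: ExpressionWeights | None = None,
                   summary: GwasSummary | None = None,
                   config: dict | None = None, gene_id: str = "gene") -> None:
    """Write a replayable snapshot of one simulated dataset."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes_tsv(geno, outdir / "genotypes.tsv")
    yv = y.y if hasattr(y, "y") else y
    write_phenotype(geno.sample_ids, yv, outdir / "phenotype.tsv")
    if weights is not None:
        write_expression_weights(weights, gene_id, outdir / "weights.tsv")
    if summary is not None:
        write_summary(summary, outdir / "summary.tsv")
    if config is not None:
        (outdir / "config.json").write_text(json.dumps(config, indent=2))


__all__ = ["AlignedGeneData", "load_genotypes", "write_genotypes_tsv",
           "load_phenotype", "write_phenotype", "load_summary",
           "write_summary", "load_expression_weights",
           "write_expression_weights", "write_prs_weights", "write_results",
           "align_gene", "export_dataset"]
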