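"""Data containers and quality control for genotype, expression and phenotype data.

Genotypes are minor-allele dosage codes (0/1/2 per sample and SNP), possibly
missing. Quality control follows the usual small-cohort GWAS recipe:

* drop SNPs with more than 10% missing calls (strictly greater),
* impute the remaining missing calls with the per-SNP mode (genotype codes
  are categorical, so the mode, not the mean, is used; ties break toward the
  smaller code),
* keep only SNPs with minor allele frequency strictly greater than 0.1.

Expression values are continuous (samples x genes) and assumed complete.
Phenotypes are binary (0 = absence, 1 = presence of disease).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPE_CODES = (0.0, 1.0, 2.0)


class NoUsableSNPsError(ValueError):
    """Raised when a QC step removes every SNP."""


class HarmonizationError(ValueError):
    """Raised when genotype/expression/phenotype samples cannot be aligned."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Samples x SNPs dosage matrix; NaN marks a missing call."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if observed.size and not np.isin(observed, GENOTYPE_CODES).all():
            bad = np.unique(observed[~np.isin(observed, GENOTYPE_CODES)])
            raise ValueError(f"genotype codes must be 0/1/2, found {bad[:5]}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate sample or SNP identifiers")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def snps(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def missing_fraction(self) -> pd.Series:
        """Per-SNP fraction of missing calls."""
        return self.data.isna().mean(axis=0)

    def maf(self) -> pd.Series:
        """Per-SNP minor allele frequency, ``min(f, 1 - f)`` with
        ``f = sum(codes) / (2 n)``; requires a complete matrix."""
        if self.data.isna().any().any():
            raise ValueError("MAF is defined on a complete (imputed) matrix")
        f = self.data.sum(axis=0) / (2.0 * self.n_samples)
        return np.minimum(f, 1.0 - f)

    def restrict(self, samples=None, snps=None) -> "GenotypeMatrix":
        data = self.data
        if samples is not None:
            data = data.loc[list(samples)]
        if snps is not None:
            data = data[list(snps)]
        return GenotypeMatrix(data)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x genes matrix of continuous expression values."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate sample or gene identifiers")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def restrict(self, samples=None, genes=None) -> "ExpressionMatrix":
        data = self.data
        if samples is not None:
            data = data.loc[list(samples)]
        if genes is not None:
            data = data[list(genes)]
        return ExpressionMatrix(data)


@dataclass(frozen=True)
class PhenotypeVector:
    """Binary disease labels indexed by sample id (0 absent, 1 present)."""

    labels: pd.Series

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        vals = self.labels.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("phenotype labels must be 0 or 1")

    @property
    def samples(self) -> list[str]:
        return list(self.labels.index)

    @property
    def values(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=float)

    def has_both_classes(self) -> bool:
        vals = self.labels.to_numpy()
        return bool((vals == 0).any() and (vals == 1).any())

    def restrict(self, samples) -> "PhenotypeVector":
        return PhenotypeVector(self.labels.loc[list(samples)])


def filter_missing_snps(
    g: GenotypeMatrix, max_missing_fraction: float = 0.10
) -> GenotypeMatrix:
    """Remove SNPs whose missing fraction is *strictly greater* than the
    threshold (default 10%); a SNP with exactly 10% missing is retained."""
    if not 0.0 <= max_missing_fraction < 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    frac = g.missing_fraction()
    keep = frac.index[frac <= max_missing_fraction]
    removed = g.data.shape[1] - len(keep)
    if removed:
        logger.info("filter_missing_snps: removed %d of %d SNPs", removed, g.data.shape[1])
    if len(keep) == 0:
        raise NoUsableSNPsError("all SNPs exceed the missingness threshold")
    return GenotypeMatrix(g.data[keep])


def impute_snps(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by that SNP's most frequent observed code.

    Ties between codes break toward the smaller code, deterministically.
    """
    data = g.data.copy()
    n_imputed = 0
    for snp in data.columns:
        col = data[snp]
        mask = col.isna()
        if not mask.any():
            continue
        observed = col[~mask]
        if observed.empty:
            raise ValueError(f"SNP {snp!r} has no observed calls; remove it upstream")
        counts = [(observed == code).sum() for code in GENOTYPE_CODES]
        mode = GENOTYPE_CODES[int(np.argmax(counts))]  # first max -> smaller code
        data.loc[mask, snp] = mode
        n_imputed += int(mask.sum())
    if n_imputed:
        logger.info("impute_snps: imputed %d missing calls", n_imputed)
    return GenotypeMatrix(data)


def filter_maf(g: GenotypeMatrix, min_maf: float = 0.1) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency *strictly greater* than
    ``min_maf`` (default 0.1); a SNP at exactly the threshold is removed."""
    maf = g.maf()
    keep = maf.index[maf > min_maf]
    removed = g.data.shape[1] - len(keep)
    if removed:
        logger.info("filter_maf: removed %d of %d SNPs", removed, g.data.shape[1])
    if len(keep) == 0:
        raise NoUsableSNPsError("no SNP passes the MAF threshold")
    return GenotypeMatrix(g.data[keep])


def qc_genotypes(
    g: GenotypeMatrix,
    max_missing_fraction: float = 0.10,
    min_maf: float = 0.1,
) -> GenotypeMatrix:
    """Full genotype QC chain: missingness filter, mode imputation, MAF filter."""
    return filter_maf(impute_snps(filter_missing_snps(g, max_missing_fraction)), min_maf)


def harmonize(
    g: GenotypeMatrix, e: ExpressionMatrix, p: PhenotypeVector
) -> tuple[GenotypeMatrix, ExpressionMatrix, PhenotypeVector]:
    """Restrict all three containers to the shared samples, in one canonical
    (sorted) order. Duplicate sample ids are rejected by the containers."""
    for c in (g.samples, e.samples, p.samples):
        if not c:
            raise HarmonizationError("empty sample list")
    common = sorted(set(g.samples) & set(e.samples) & set(p.samples))
    if not common:
        raise HarmonizationError("no samples shared across genotype/expression/phenotype")
    dropped = max(len(g.samples), len(e.samples), len(p.samples)) - len(common)
    if dropped:
        logger.info("harmonize: %d shared samples retained", len(common))
    return g.restrict(samples=common), e.restrict(samples=common), p.restrict(common)
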