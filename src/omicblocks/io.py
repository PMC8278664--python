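"""Readers and writers for the pipeline's plain-text input formats.

* genotype TSV: rows = SNPs, columns = samples, cells in {0, 1, 2, NA};
* expression TSV: rows = genes, columns = samples, real values;
* phenotype TSV: two columns (sample_id, label in {0, 1});
* PPI TSV: two columns of gene ids (PICKLE-style edge list);
* eQTL TSV: columns snp_id, gene_id, tissue and optionally a significance
  column (GTEx-like significant-pairs layout).

An optional VCF genotype reader maps GT fields to minor-allele dosage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .blocks import EqtlTable
from .preprocess import ExpressionMatrix, GenotypeMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

_NA = ["NA", "NaN", ""]


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA)
    g = GenotypeMatrix(df.T.astype(float))
    n_missing = int(g.data.isna().sum().sum())
    logger.info(
        "read_genotype_tsv: %d samples x %d SNPs (%d missing calls)",
        g.data.shape[0], g.data.shape[1], n_missing,
    )
    return g


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    out = g.data.T
    out.index.name = "snp_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA)
    e = ExpressionMatrix(df.T.astype(float))
    logger.info("read_expression_tsv: %d samples x %d genes", *e.data.shape)
    return e


def write_expression_tsv(e: ExpressionMatrix, path) -> None:
    out = e.data.T
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_phenotype_tsv(path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype TSV needs (sample_id, label) columns")
    labels = pd.Series(
        df.iloc[:, 1].astype(int).to_numpy(), index=df.iloc[:, 0].astype(str)
    )
    logger.info(
        "read_phenotype_tsv: %d samples (%d cases)", len(labels), int(labels.sum())
    )
    return PhenotypeVector(labels)


def write_phenotype_tsv(p: PhenotypeVector, path) -> None:
    pd.DataFrame({"sample_id": p.samples, "label": p.labels.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_ppi_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] in ("gene_a", "gene1", "protein_a"):
        df = df.iloc[1:]
    edges = [tuple(row) for row in df.iloc[:, :2].itertuples(index=False)]
    logger.info("read_ppi_tsv: %d edges", len(edges))
    return edges


def write_ppi_tsv(edges, path) -> None:
    pd.DataFrame(edges).to_csv(path, sep="\t", index=False, header=["gene_a", "gene_b"])


def read_eqtl_tsv(path) -> EqtlTable:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str, "tissue": str})
    t = EqtlTable(df)
    logger.info("read_eqtl_tsv: %d records, tissues %s", len(t), t.tissues)
    return t


def write_eqtl_tsv(t: EqtlTable, path) -> None:
    t.records.to_csv(path, sep="\t", index=False)


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF, coding GT as alternate-allele dosage
    (./., .|. -> missing). Requires the optional cyvcf2 dependency."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("reading VCF requires the 'vcf' extra (cyvcf2)") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, columns = [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        gts = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=missing?,3=hom alt
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        dosage = np.where(gts == 3, 2.0, np.where(gts == 2, np.nan, gts))
        snp_ids.append(vid)
        columns.append(dosage)
    data = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=samples,
        columns=snp_ids,
    )
    logger.info("read_genotype_vcf: %d samples x %d variants", *data.shape)
    return GenotypeMatrix(data)
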