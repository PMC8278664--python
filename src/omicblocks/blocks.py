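"""eQTL-driven assembly of three-layer SNP-gene-phenotype blocks.

Each screened gene cluster is mapped to its SNP cluster: the union of SNPs
with an eQTL record to any gene of the cluster (tissue-filtered, restricted
to QC-passed SNPs, lexicographically ordered). A *block* bundles the SNP
cluster, the gene cluster and the phenotype with consistently sliced
genotype/expression views; blocks are the units on which the SNP->gene and
gene->phenotype models are fitted. The same SNP may legitimately appear in
several blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .network import GeneCluster
from .preprocess import ExpressionMatrix, GenotypeMatrix, PhenotypeVector

logger = logging.getLogger(__name__)


class UnknownTissueError(ValueError):
    """Requested tissue absent from the eQTL table."""


class BlockAssemblyError(RuntimeError):
    """No block could be assembled (nothing to fit)."""


@dataclass(frozen=True)
class EqtlTable:
    """SNP -> gene eQTL associations with a tissue label.

    Columns: ``snp_id``, ``gene_id``, ``tissue`` and optionally a
    significance column (e.g. a q-value). Duplicate records are collapsed.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "gene_id", "tissue"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"eQTL table missing columns: {sorted(missing)}")
        deduped = self.records.drop_duplicates(
            subset=["snp_id", "gene_id", "tissue"]
        ).reset_index(drop=True)
        object.__setattr__(self, "records", deduped)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.records["tissue"].unique())

    def filter_significance(self, column: str, threshold: float) -> "EqtlTable":
        """Keep records whose significance value is <= threshold (the default
        pipeline uses every provided record; no cut-off is applied)."""
        if column not in self.records.columns:
            raise ValueError(f"no significance column {column!r}")
        kept = self.records[self.records[column] <= threshold]
        logger.info("filter_significance: %d of %d records kept", len(kept), len(self))
        return EqtlTable(kept.reset_index(drop=True))


def filter_eqtl_by_tissue(t: EqtlTable, tissue: str) -> EqtlTable:
    """Restrict the table to one tissue; unknown labels raise with the
    available vocabulary, an empty (but known-tissue) result is flagged."""
    if tissue not in set(t.records["tissue"]):
        raise UnknownTissueError(
            f"tissue {tissue!r} not in table; available: {t.tissues}"
        )
    kept = t.records[t.records["tissue"] == tissue].reset_index(drop=True)
    if kept.empty:
        logger.warning("filter_eqtl_by_tissue: no record for tissue %r", tissue)
    return EqtlTable(kept)


def map_snp_cluster(
    c: GeneCluster, t: EqtlTable, g: GenotypeMatrix
) -> list[str]:
    """SNPs with an eQTL record to any gene of the cluster, restricted to the
    genotype panel, lexicographically ordered."""
    hits = t.records[t.records["gene_id"].isin(c.genes)]
    mapped = set(hits["snp_id"])
    panel = set(g.snps)
    absent = len(mapped - panel)
    if absent:
        logger.info(
            "map_snp_cluster[%s]: %d mapped SNPs absent from the genotype panel",
            c.cluster_id, absent,
        )
    return sorted(mapped & panel)


@dataclass(frozen=True)
class Block:
    """One three-layer unit: SNP cluster + gene cluster + phenotype."""

    block_id: str
    snp_ids: tuple
    gene_cluster: GeneCluster
    genotype_view: pd.DataFrame  # samples x snp_ids
    expression_view: pd.DataFrame  # samples x genes
    phenotype: PhenotypeVector

    def __post_init__(self) -> None:
        if not self.snp_ids:
            raise ValueError("block has no SNPs")
        if self.expression_view.shape[1] == 0:
            raise ValueError("block has no genes")
        if not (
            list(self.genotype_view.index)
            == list(self.expression_view.index)
            == self.phenotype.samples
        ):
            raise ValueError("block views are not sample-aligned")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression_view.columns)


def assemble_blocks(
    selected: list[GeneCluster],
    t: EqtlTable,
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    p: PhenotypeVector,
) -> list[Block]:
    """One block per selected cluster with a non-empty SNP mapping; clusters
    without mappable SNPs are dropped with a log entry. Zero blocks is a
    pipeline error (nothing to fit)."""
    if not (g.samples == e.samples == p.samples):
        raise ValueError("inputs are not harmonized (sample order differs)")
    blocks: list[Block] = []
    dropped = 0
    expr_genes = set(e.genes)
    for c in selected:
        snps = map_snp_cluster(c, t, g)
        genes = sorted(c.genes & expr_genes)
        if not snps or not genes:
            dropped += 1
            logger.info("assemble_blocks: cluster %s dropped (no mappable SNPs)", c.cluster_id)
            continue
        blocks.append(
            Block(
                block_id=f"B_{c.cluster_id}",
                snp_ids=tuple(snps),
                gene_cluster=c,
                genotype_view=g.data[snps],
                expression_view=e.data[genes],
                phenotype=p,
            )
        )
    if dropped:
        logger.info("assemble_blocks: %d clusters dropped", dropped)
    if not blocks:
        raise BlockAssemblyError("no block could be assembled from the selected clusters")
    return blocks


def block_manifest(blocks: list[Block]) -> pd.DataFrame:
    """Summary table (block_id, n_snps, n_genes)."""
    return pd.DataFrame(
        {
            "block_id": [b.block_id for b in blocks],
            "n_snps": [len(b.snp_ids) for b in blocks],
            "n_genes": [len(b.gene_ids) for b in blocks],
        }
    )
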