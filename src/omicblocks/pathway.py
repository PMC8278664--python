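"""Pathway Scores: ranking SNP -> gene -> phenotype paths.

The Pathway Score (PS) of a (SNP, gene) pair multiplies the two fitted edge
weights along the path: the sparse-PLS SNP->gene coefficient magnitude and
the group-lasso gene->phenotype coefficient magnitude. An absent edge
contributes weight zero, so a pathway through an unselected cluster or an
inactive SNP scores exactly 0. Both factors are taken on the standardized
scale, in absolute value; when a SNP appears in several blocks the maximum
PS for the pair is kept. The per-block logistic coefficient is carried as
an auxiliary diagnostic column.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .grouplasso import GroupLassoFit


@dataclass(frozen=True)
class PathwayRecord:
    """One SNP-gene-phenotype path and its multiplicative score."""

    snp_id: str
    gene_id: str
    ps: float
    snp_gene_weight: float
    gene_phenotype_weight: float
    block_id: str
    block_logistic_weight: float


def compute_ps(block_models, gl_fit: GroupLassoFit) -> list[PathwayRecord]:
    """One record per (SNP, gene) pair with a nonzero SPLS coefficient in any
    block; duplicates across blocks keep the maximum PS."""
    gl_coef = gl_fit.coefficients
    best: dict[tuple[str, str], PathwayRecord] = {}
    for bm in block_models:
        B = bm.spls.coefficients
        logistic = pd.Series(bm.gene_logistic.coef, index=bm.gene_logistic.gene_ids)
        for gene in B.columns:
            gw = abs(float(gl_coef.get(gene, 0.0)))
            bw = float(logistic.get(gene, 0.0))
            col = B[gene]
            for snp, sw in col[col != 0.0].items():
                rec = PathwayRecord(
                    snp_id=snp,
                    gene_id=gene,
                    ps=abs(float(sw)) * gw,
                    snp_gene_weight=abs(float(sw)),
                    gene_phenotype_weight=gw,
                    block_id=bm.block_id,
                    block_logistic_weight=bw,
                )
                prev = best.get((snp, gene))
                if prev is None or rec.ps > prev.ps:
                    best[(snp, gene)] = rec
    return sorted(best.values(), key=lambda r: (r.snp_id, r.gene_id))


def rank_pathways(records: list[PathwayRecord], top_n: int) -> list[PathwayRecord]:
    """Top pathways by descending PS; zero-score records are excluded and
    ties break by (snp_id, gene_id) for run-to-run determinism."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    nonzero = [r for r in records if r.ps > 0.0]
    ordered = sorted(nonzero, key=lambda r: (-r.ps, r.snp_id, r.gene_id))
    return ordered[:top_n]


def pathway_table(records: list[PathwayRecord]) -> pd.DataFrame:
    """Ranked table in the (rank, snp, gene, ps, weights) layout."""
    ordered = sorted(
        [r for r in records if r.ps > 0.0],
        key=lambda r: (-r.ps, r.snp_id, r.gene_id),
    )
    return pd.DataFrame(
        {
            "rank": range(1, len(ordered) + 1),
            "snp_id": [r.snp_id for r in ordered],
            "gene_id": [r.gene_id for r in ordered],
            "ps": [r.ps for r in ordered],
            "snp_gene_weight": [r.snp_gene_weight for r in ordered],
            "gene_phenotype_weight": [r.gene_phenotype_weight for r in ordered],
            "block_logistic_weight": [r.block_logistic_weight for r in ordered],
        }
    )
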