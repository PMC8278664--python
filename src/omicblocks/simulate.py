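"""Synthetic genotype/expression/eQTL/PPI/phenotype generator with ground truth.

The generator emulates the data regime the pipeline targets: a small cohort
(tens of samples), a SNP panel with minor allele frequencies in (0.1, 0.5),
and gene expression organised into co-expression clusters. Its genetic
architecture is *regulatory-hub* style: each gene cluster carries a few
regulatory eQTL SNPs, each of which additively shifts the expression of
every gene in its cluster (effect = per-pair coefficient x dosage). On top
of that a shared latent factor induces the within-cluster correlation, and
independent Gaussian noise is added. PPI edges are emitted for all
within-cluster pairs plus a configurable fraction of random inter-cluster
pairs.

The binary phenotype follows a logistic model on the standardized
expression of the genes in a few *causal* clusters; the intercept is tuned
so the class balance is ~0.5. One (SNP, gene) pair per dataset — the
"driver" — receives a boosted eQTL effect and the largest phenotype
coefficient, so every simulated dataset has a well-identified strongest
pathway for recovery benchmarks.

All three generators are deterministic given ``SimulationConfig.seed``; the
emitted eQTL table lists exactly the planted SNP -> gene pairs recorded in
the ground-truth manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .blocks import EqtlTable
from .network import GeneCluster
from .preprocess import ExpressionMatrix, GenotypeMatrix, PhenotypeVector

#: multiplier on eqtl_effect_size for the driver (snp, gene) pair
DRIVER_EFFECT_BOOST = 6.0
#: multiplier on the driver SNP's effects on the rest of its cluster (a
#: boosted regulatory hub, so the driver SNP carries the block's leading
#: latent component)
DRIVER_SNP_BOOST = 2.0
#: multiplier on phenotype_effect_size for the driver gene (jitter tops at 1.5)
DRIVER_GAMMA_BOOST = 6.0

TISSUE_LABEL = "synthetic"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the default benchmark: 80 samples, 200 SNPs, 200 genes
    in 20 clusters of 10, 3 causal clusters, 5 regulatory eQTL SNPs per
    cluster.
    """

    n_samples: int = 80
    n_snps: int = 200
    n_genes: int = 200
    n_clusters: int = 20
    cluster_size_range: tuple = (5, 100)
    n_causal_clusters: int = 3
    eqtl_effect_size: float = 2.0
    within_cluster_correlation: float = 0.5
    noise_sd: float = 1.0
    maf_range: tuple = (0.1, 0.5)
    #: allele-frequency range for the planted regulatory (eQTL) SNPs; kept
    #: strictly inside the MAF-filter band so QC cannot delete the planted
    #: ground truth (regulatory variants are modelled as common variants)
    eqtl_maf_range: tuple = (0.15, 0.45)
    n_eqtl_snps_per_cluster: int = 5
    phenotype_effect_size: float = 0.3
    inter_cluster_edge_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
        if self.n_causal_clusters > self.n_clusters:
            raise ValueError("n_causal_clusters must be <= n_clusters")
        if not 0.0 < self.within_cluster_correlation < 1.0:
            raise ValueError("within_cluster_correlation must be in (0, 1)")
        if self.n_snps < self.n_clusters * self.n_eqtl_snps_per_cluster:
            raise ValueError("not enough SNPs for the per-cluster eQTL hubs")
        size = self.n_genes // self.n_clusters
        if not self.cluster_size_range[0] <= size <= self.cluster_size_range[1]:
            raise ValueError("cluster sizes infeasible for n_genes/n_clusters")

    def cluster_sizes(self) -> list[int]:
        base = self.n_genes // self.n_clusters
        rem = self.n_genes % self.n_clusters
        return [base + (1 if i < rem else 0) for i in range(self.n_clusters)]


@dataclass
class GroundTruth:
    """Planted structure of one simulated dataset."""

    causal_clusters: tuple
    causal_pathways: pd.DataFrame  # snp_id, gene_id, effect
    true_eqtl_map: pd.DataFrame
    driver_snp: str
    driver_gene: str
    cluster_of_gene: dict
    snp_freqs: pd.Series
    gene_effects: pd.Series | None = None  # phenotype coefficients, causal genes
    alpha: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "causal_clusters": list(self.causal_clusters),
                "causal_pathways": self.causal_pathways.to_dict(orient="records"),
                "driver_snp": self.driver_snp,
                "driver_gene": self.driver_gene,
                "cluster_of_gene": self.cluster_of_gene,
                "snp_freqs": self.snp_freqs.to_dict(),
                "gene_effects": None
                if self.gene_effects is None
                else self.gene_effects.to_dict(),
                "alpha": self.alpha,
            }
        )


class Dataset(NamedTuple):
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    phenotype: PhenotypeVector
    ppi_edges: list
    eqtl: EqtlTable
    clusters: list
    truth: GroundTruth


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stage,)))


def _snp_name(i: int) -> str:
    return f"rs{i + 1:06d}"


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def _cluster_name(i: int) -> str:
    return f"T{i + 1:02d}"  # T = true (planted) cluster


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, pd.Series]:
    """Dosages ~ Binomial(2, f) per SNP with f drawn uniformly from
    ``maf_range``; returns the matrix and the drawn frequencies."""
    rng = _rng(cfg, 0)
    freqs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    # the leading panel slice holds the regulatory hub SNPs (see
    # simulate_expression); draw their frequencies from the common-variant
    # band so the planted truth survives the MAF filter
    n_hub = cfg.n_clusters * cfg.n_eqtl_snps_per_cluster
    freqs[:n_hub] = rng.uniform(*cfg.eqtl_maf_range, size=n_hub)
    dosages = rng.binomial(2, freqs, size=(cfg.n_samples, cfg.n_snps)).astype(float)
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    snps = [_snp_name(i) for i in range(cfg.n_snps)]
    g = GenotypeMatrix(pd.DataFrame(dosages, index=samples, columns=snps))
    return g, pd.Series(freqs, index=snps)


def simulate_expression(
    cfg: SimulationConfig, g: GenotypeMatrix, snp_freqs: pd.Series | None = None
) -> tuple[ExpressionMatrix, list[GeneCluster], EqtlTable, list, GroundTruth]:
    """Cluster-structured expression driven by planted regulatory eQTLs.

    Returns (expression, planted clusters, eQTL table, PPI edges, truth).
    """
    rng = _rng(cfg, 1)
    n = cfg.n_samples
    sizes = cfg.cluster_sizes()
    gene_names = [_gene_name(i) for i in range(cfg.n_genes)]
    rho = cfg.within_cluster_correlation

    clusters: list[GeneCluster] = []
    cluster_of_gene: dict[str, str] = {}
    start = 0
    members: list[list[str]] = []
    for ci, size in enumerate(sizes):
        genes = gene_names[start : start + size]
        start += size
        cid = _cluster_name(ci)
        members.append(genes)
        clusters.append(GeneCluster(cid, frozenset(genes), float("nan")))
        for gname in genes:
            cluster_of_gene[gname] = cid

    causal_idx = np.sort(
        rng.choice(cfg.n_clusters, size=cfg.n_causal_clusters, replace=False)
    )
    causal_clusters = tuple(_cluster_name(i) for i in causal_idx)

    # regulatory hub SNPs: cluster ci owns a contiguous slice of the panel
    m = cfg.n_eqtl_snps_per_cluster
    hub_snps = {
        _cluster_name(ci): [_snp_name(ci * m + j) for j in range(m)]
        for ci in range(cfg.n_clusters)
    }

    # Per-pair effect sizes with multiplicative jitter in [0.5, 1.5]. The
    # driver pathway is a dominant regulatory variant: the driver SNP's
    # effects on its whole cluster are boosted (it carries the block's
    # leading latent component) and the driver gene responds to the driver
    # SNP only, with the largest effect, so its expression is almost
    # entirely driven by that one SNP (plus the shared cluster factor,
    # which keeps it co-clustered with its neighbours).
    records = []
    driver_cluster = causal_clusters[0]
    driver_gene = str(rng.choice(members[causal_idx[0]]))
    driver_snp = str(rng.choice(hub_snps[driver_cluster]))
    for ci in range(cfg.n_clusters):
        cid = _cluster_name(ci)
        for snp in hub_snps[cid]:
            for gname in members[ci]:
                eff = cfg.eqtl_effect_size * rng.uniform(0.5, 1.5)
                if gname == driver_gene:
                    if snp != driver_snp:
                        continue  # no other eQTL for the driver gene
                    eff = cfg.eqtl_effect_size * DRIVER_EFFECT_BOOST
                elif snp == driver_snp:
                    eff *= DRIVER_SNP_BOOST
                records.append({"snp_id": snp, "gene_id": gname, "effect": eff})
    effects = pd.DataFrame(records)

    # expression: eQTL part + latent cluster factor + idiosyncratic noise
    dosage = g.data.to_numpy(dtype=float)
    dosage_c = dosage - dosage.mean(axis=0)
    snp_pos = {s: i for i, s in enumerate(g.snps)}
    expr = np.zeros((n, cfg.n_genes))
    gene_pos = {gname: i for i, gname in enumerate(gene_names)}
    for rec in records:
        expr[:, gene_pos[rec["gene_id"]]] += rec["effect"] * dosage_c[:, snp_pos[rec["snp_id"]]]
    factors = rng.normal(size=(n, cfg.n_clusters))
    eps = rng.normal(size=(n, cfg.n_genes))
    for ci, genes in enumerate(members):
        idx = [gene_pos[gname] for gname in genes]
        expr[:, idx] += cfg.noise_sd * (
            np.sqrt(rho) * factors[:, [ci]] + np.sqrt(1.0 - rho) * eps[:, idx]
        )
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=g.samples, columns=gene_names)
    )

    # PPI: all within-cluster pairs plus random inter-cluster pairs
    ppi: list[tuple[str, str]] = []
    for genes in members:
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                ppi.append((genes[i], genes[j]))
    n_inter = int(round(cfg.inter_cluster_edge_fraction * len(ppi)))
    made = 0
    guard = 0
    existing = set(ppi)
    while made < n_inter and guard < 50 * max(n_inter, 1):
        guard += 1
        a, b = rng.choice(cfg.n_genes, size=2, replace=False)
        u, v = gene_names[a], gene_names[b]
        if cluster_of_gene[u] == cluster_of_gene[v]:
            continue
        key = (u, v) if u <= v else (v, u)
        if key in existing:
            continue
        existing.add(key)
        ppi.append(key)
        made += 1

    eqtl = EqtlTable(
        effects[["snp_id", "gene_id"]].assign(tissue=TISSUE_LABEL)
    )
    truth = GroundTruth(
        causal_clusters=causal_clusters,
        causal_pathways=effects,
        true_eqtl_map=effects,
        driver_snp=driver_snp,
        driver_gene=driver_gene,
        cluster_of_gene=cluster_of_gene,
        snp_freqs=snp_freqs
        if snp_freqs is not None
        else pd.Series(np.nan, index=g.snps),
    )
    return expression, clusters, eqtl, ppi, truth


def simulate_phenotype(
    cfg: SimulationConfig, e: ExpressionMatrix, truth: GroundTruth
) -> PhenotypeVector:
    """Labels ~ Bernoulli(logistic(alpha + sum of causal-gene effects)) with
    alpha tuned so the class balance is ~0.5. Phenotype coefficients act on
    standardized expression; the driver gene gets the largest coefficient.
    Records the drawn coefficients and alpha in ``truth``."""
    rng = _rng(cfg, 2)
    causal_genes = sorted(
        gname
        for gname, cid in truth.cluster_of_gene.items()
        if cid in truth.causal_clusters
    )
    gammas = pd.Series(
        cfg.phenotype_effect_size * rng.uniform(0.5, 1.5, size=len(causal_genes)),
        index=causal_genes,
    )
    gammas[truth.driver_gene] = cfg.phenotype_effect_size * DRIVER_GAMMA_BOOST
    vals = e.data[causal_genes].to_numpy(dtype=float)
    z = (vals - vals.mean(axis=0)) / np.where(vals.std(axis=0) == 0, 1, vals.std(axis=0))
    eta = z @ gammas.to_numpy()

    def balance(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(eta + alpha))))) - 0.5

    alpha = brentq(balance, -50.0, 50.0)
    labels = (rng.uniform(size=len(eta)) < 1.0 / (1.0 + np.exp(-(eta + alpha)))).astype(int)
    truth.gene_effects = gammas
    truth.alpha = float(alpha)
    return PhenotypeVector(pd.Series(labels, index=e.samples))


def simulate_dataset(cfg: SimulationConfig | None = None, **overrides) -> Dataset:
    """Generate a full dataset (genotypes, expression, phenotype, PPI, eQTL)
    with its ground-truth manifest."""
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    elif overrides:
        raise ValueError("pass either cfg or keyword overrides, not both")
    g, freqs = simulate_genotypes(cfg)
    e, clusters, eqtl, ppi, truth = simulate_expression(cfg, g, freqs)
    p = simulate_phenotype(cfg, e, truth)
    return Dataset(g, e, p, ppi, eqtl, clusters, truth)


def inject_missingness(
    g: GenotypeMatrix,
    cfg: SimulationConfig,
    snp_fraction: float = 0.2,
    rate_range: tuple = (0.05, 0.15),
) -> GenotypeMatrix:
    """Set a random 5-15% of calls to missing for a fraction of SNPs, to
    exercise the QC path."""
    rng = _rng(cfg, 3)
    data = g.data.copy()
    snps = list(data.columns)
    chosen = rng.choice(snps, size=int(round(snp_fraction * len(snps))), replace=False)
    for snp in chosen:
        rate = rng.uniform(*rate_range)
        mask = rng.uniform(size=len(data)) < rate
        data.loc[mask, snp] = np.nan
    return GenotypeMatrix(data)


def write_dataset(dataset: Dataset, outdir) -> None:
    """Write the five pipeline input files plus truth.json."""
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_genotype_tsv(dataset.genotypes, outdir / "genotype.tsv")
    io.write_expression_tsv(dataset.expression, outdir / "expression.tsv")
    io.write_phenotype_tsv(dataset.phenotype, outdir / "phenotype.tsv")
    io.write_ppi_tsv(dataset.ppi_edges, outdir / "ppi.tsv")
    io.write_eqtl_tsv(dataset.eqtl, outdir / "eqtl.tsv")
    (outdir / "truth.json").write_text(dataset.truth.to_json())
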