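"""Block-ensemble model: the package's Model/Results surface.

``BlockEnsemble`` is built from harmonized genotype, expression, phenotype,
PPI and eQTL inputs; ``fit()`` runs the full chain

    weighted gene network -> SPICi clusters -> group-lasso screening
    -> eQTL block assembly -> per-block SPLS (SNP->gene) + logistic
       (gene->phenotype)

and returns a ``BlockEnsembleResults`` carrying the fitted pieces, block
predictions (averaged into the ensemble probability) and pathway scores.
``fit_cv()`` repeats the whole chain inside each stratified training fold,
so screening and model fitting never see held-out samples, and returns
out-of-fold probabilities with their pooled ROC/AUC.

Prediction path: the gene->phenotype logistic layer is trained on observed
expression but applied, at prediction time, to the SPLS-predicted
expression, so a new sample needs genotypes only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from . import evaluation
from .blocks import Block, BlockAssemblyError, EqtlTable, assemble_blocks, filter_eqtl_by_tissue
from .grouplasso import GroupLassoFit, fit_group_lasso, screen_clusters, select_lambda
from .network import GeneCluster, SpiciParams, build_network, spici_cluster, tune_clustering
from .pathway import compute_ps, pathway_table, rank_pathways
from .preprocess import ExpressionMatrix, GenotypeMatrix, PhenotypeVector, harmonize
from .spls import SPLSModel, fit_spls, select_spls_params

logger = logging.getLogger(__name__)


class EmptySelectionError(RuntimeError):
    """Group-lasso screening selected no cluster."""


@dataclass
class GeneLogistic:
    """Ridge-stabilized logistic layer from (standardized) gene expression to
    the binary phenotype. ``ridge`` is the l2 penalty strength (sklearn's
    C = 1/ridge); it keeps coefficients finite under perfect separation or
    duplicated genes."""

    gene_ids: list
    coef: np.ndarray
    intercept: float
    y_mean: np.ndarray
    y_scale: np.ndarray
    ridge: float

    def predict_proba(self, Y_new: pd.DataFrame) -> np.ndarray:
        Z = (Y_new[self.gene_ids].to_numpy(dtype=float) - self.y_mean) / self.y_scale
        eta = Z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def fit_gene_logistic(
    Y: pd.DataFrame, p: PhenotypeVector, ridge: float = 0.01
) -> GeneLogistic:
    """Fit the gene -> phenotype logistic layer on observed expression."""
    if not p.has_both_classes():
        raise ValueError("both phenotype classes must be present")
    vals = Y.to_numpy(dtype=float)
    y_mean = vals.mean(axis=0)
    y_scale = vals.std(axis=0)
    y_scale = np.where(y_scale == 0.0, 1.0, y_scale)
    Z = (vals - y_mean) / y_scale
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
    clf.fit(Z, p.values)
    return GeneLogistic(
        gene_ids=list(Y.columns),
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        y_mean=y_mean,
        y_scale=y_scale,
        ridge=ridge,
    )


@dataclass
class BlockModel:
    """Fitted three-layer model for a single block."""

    block_id: str
    spls: SPLSModel
    gene_logistic: GeneLogistic


def fit_block(
    block: Block,
    eta: float = 0.5,
    K: int = 2,
    ridge: float = 10.0,
    tune: bool = False,
    seed: int = 0,
) -> BlockModel:
    """Fit SPLS (SNP->gene) and logistic (gene->phenotype) layers for one block."""
    if tune:
        eta, K = select_spls_params(block.genotype_view, block.expression_view, seed=seed)
    spls = fit_spls(block.genotype_view, block.expression_view, eta=eta, K=K)
    gl = fit_gene_logistic(block.expression_view, block.phenotype, ridge=ridge)
    return BlockModel(block_id=block.block_id, spls=spls, gene_logistic=gl)


def predict_block(m: BlockModel, X_new: pd.DataFrame) -> np.ndarray:
    """Probability of disease for new samples from their genotypes:
    expression predicted through the SPLS map, then the logistic layer."""
    Yhat = m.spls.predict_expression(X_new)
    return m.gene_logistic.predict_proba(Yhat)


@dataclass
class EnsemblePrediction:
    """Per-block probabilities and their arithmetic mean."""

    per_block: dict
    final: np.ndarray
    sample_ids: list = field(default_factory=list)


def average_predictions(preds) -> EnsemblePrediction:
    """Element-wise arithmetic mean of per-block probability vectors.

    ``preds`` is a mapping block_id -> vector or a list of vectors."""
    if isinstance(preds, dict):
        items = list(preds.items())
    else:
        items = [(f"block{i}", v) for i, v in enumerate(preds)]
    if not items:
        raise ValueError("no block predictions to average")
    lengths = {len(np.asarray(v)) for _, v in items}
    if len(lengths) != 1:
        raise ValueError("block prediction vectors differ in length")
    stacked = np.vstack([np.asarray(v, dtype=float) for _, v in items])
    return EnsemblePrediction(per_block=dict(items), final=stacked.mean(axis=0))


@dataclass
class PipelineConfig:
    """Hyperparameters of the full chain.

    spici: clustering hyperparameters (``tune_spici`` scans the grid instead).
    lambda_: group-lasso penalty; None selects it by stratified CV on AUC.
    eta, K: SPLS sparsity and component count (``tune_spls`` cross-validates
    them per block). ridge: l2 strength of the gene->phenotype logistic.
    """

    spici: SpiciParams = field(default_factory=SpiciParams)
    tune_spici: bool = False
    lambda_: float | None = None
    n_lambda: int = 10
    lambda_min_ratio: float = 0.05
    screen_folds: int = 3
    eta: float = 0.5
    K: int = 2
    tune_spls: bool = False
    ridge: float = 10.0
    tissue: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spici_kwargs = raw.pop("spici", None)
        cfg = cls(**raw)
        if spici_kwargs:
            cfg.spici = SpiciParams(**spici_kwargs)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


class BlockEnsemble:
    """Three-layer genotype -> expression -> phenotype block-ensemble model.

    Parameters
    ----------
    genotypes, expression, phenotype : QC-passed containers; they are
        harmonized (shared samples, one canonical order) on construction.
    ppi_edges : iterable of gene-id pairs.
    eqtl : EqtlTable (tissue-filtered here when ``config.tissue`` is set).
    config : PipelineConfig, defaults used when omitted.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        expression: ExpressionMatrix,
        phenotype: PhenotypeVector,
        ppi_edges,
        eqtl: EqtlTable,
        config: PipelineConfig | None = None,
    ) -> None:
        self.config = config or PipelineConfig()
        g, e, p = harmonize(genotypes, expression, phenotype)
        self.genotypes, self.expression, self.phenotype = g, e, p
        self.ppi_edges = [tuple(pair) for pair in ppi_edges]
        self.eqtl = (
            filter_eqtl_by_tissue(eqtl, self.config.tissue)
            if self.config.tissue is not None
            else eqtl
        )

    @classmethod
    def from_files(
        cls,
        genotype_tsv,
        expression_tsv,
        phenotype_tsv,
        ppi_tsv,
        eqtl_tsv,
        config: PipelineConfig | None = None,
        qc: bool = True,
    ) -> "BlockEnsemble":
        from . import io
        from .preprocess import qc_genotypes

        g = io.read_genotype_tsv(genotype_tsv)
        if qc:
            g = qc_genotypes(g)
        return cls(
            g,
            io.read_expression_tsv(expression_tsv),
            io.read_phenotype_tsv(phenotype_tsv),
            io.read_ppi_tsv(ppi_tsv),
            io.read_eqtl_tsv(eqtl_tsv),
            config=config,
        )

    # -- fitting ---------------------------------------------------------

    def fit(self, seed: int = 0) -> "BlockEnsembleResults":
        """Fit the full chain on all samples."""
        return self._fit_on(self.genotypes, self.expression, self.phenotype, seed)

    def _fit_on(
        self,
        g: GenotypeMatrix,
        e: ExpressionMatrix,
        p: PhenotypeVector,
        seed: int,
    ) -> "BlockEnsembleResults":
        cfg = self.config
        net = build_network(e, self.ppi_edges)
        if cfg.tune_spici:
            spici_params, clusters = tune_clustering(net)
        else:
            spici_params, clusters = cfg.spici, spici_cluster(net, cfg.spici)
        if not clusters:
            raise EmptySelectionError("clustering produced no gene cluster")
        lam = cfg.lambda_
        if lam is None:
            lam = select_lambda(
                e, clusters, p,
                n_folds=cfg.screen_folds, n_lambda=cfg.n_lambda,
                min_ratio=cfg.lambda_min_ratio, seed=seed,
            )
        gl_fit = fit_group_lasso(e, clusters, p, lam, raise_on_fail=False)
        selected = screen_clusters(gl_fit, clusters)
        if not selected:
            raise EmptySelectionError("group-lasso screening selected no cluster")
        blocks = assemble_blocks(selected, self.eqtl, g, e, p)
        block_models = [
            fit_block(b, eta=cfg.eta, K=cfg.K, ridge=cfg.ridge,
                      tune=cfg.tune_spls, seed=seed)
            for b in blocks
        ]
        return BlockEnsembleResults(
            config=cfg,
            spici_params=spici_params,
            network=net,
            clusters=clusters,
            group_lasso=gl_fit,
            selected_clusters=selected,
            blocks=blocks,
            block_models=block_models,
            seed=seed,
        )

    def fit_cv(self, n_folds: int = 5, seed: int = 0) -> "CVResults":
        """Stratified k-fold cross-validation of the whole chain.

        Screening, block building and model fitting run inside each training
        fold only. A fold whose training data yields no selected cluster (or
        no block) contributes a constant 0.5 probability for its held-out
        samples; this is the uninformative-prior fallback and is logged.
        """
        y = self.phenotype.values
        samples = np.asarray(self.phenotype.samples)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        oof = np.full(len(y), np.nan)
        folds = []
        for k, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            if len(set(y[tr])) < 2 or len(set(y[te])) < 2:
                raise ValueError(f"fold {k} has a single phenotype class")
            g_tr = self.genotypes.restrict(samples=samples[tr])
            e_tr = self.expression.restrict(samples=samples[tr])
            p_tr = self.phenotype.restrict(samples[tr])
            try:
                res = self._fit_on(g_tr, e_tr, p_tr, seed=seed * 1000 + k)
                g_te = self.genotypes.restrict(samples=samples[te])
                oof[te] = res.predict(g_te).final
            except (EmptySelectionError, BlockAssemblyError) as exc:
                logger.warning("fold %d: %s; predicting 0.5", k, exc)
                oof[te] = 0.5
            folds.append((tr, te))
        return CVResults(
            oof_probabilities=pd.Series(oof, index=samples),
            phenotype=self.phenotype,
            folds=folds,
            n_folds=n_folds,
            seed=seed,
        )


@dataclass
class BlockEnsembleResults:
    """Fitted block ensemble: estimates, block models and pathway scores."""

    config: PipelineConfig
    spici_params: SpiciParams
    network: object
    clusters: list
    group_lasso: GroupLassoFit
    selected_clusters: list
    blocks: list
    block_models: list
    seed: int

    def predict(self, genotypes: GenotypeMatrix | pd.DataFrame) -> EnsemblePrediction:
        """Ensemble probability of disease from genotypes only."""
        X = genotypes.data if isinstance(genotypes, GenotypeMatrix) else genotypes
        per_block = {
            m.block_id: predict_block(m, X) for m in self.block_models
        }
        pred = average_predictions(per_block)
        pred.sample_ids = list(X.index)
        return pred

    def pathway_records(self):
        return compute_ps(self.block_models, self.group_lasso)

    def pathway_scores(self, top_n: int | None = None) -> pd.DataFrame:
        """Ranked pathway table; ``top_n`` truncates it."""
        records = self.pathway_records()
        if top_n is not None:
            records = rank_pathways(records, top_n)
        return pathway_table(records)

    def summary(self) -> str:
        lines = [
            "Block-ensemble model of genotype-phenotype association",
            "=" * 56,
            f"samples: {len(self.blocks[0].phenotype.samples)}",
            f"gene clusters: {len(self.clusters)} "
            f"(SPICi density>={self.spici_params.min_cluster_density}, "
            f"support>={self.spici_params.min_support_threshold}, "
            f"size>={self.spici_params.min_cluster_size})",
            f"group-lasso lambda: {self.group_lasso.lambda_:.4g} "
            f"({'converged' if self.group_lasso.converged else 'iteration cap'})",
            f"selected clusters: {len(self.selected_clusters)} of {len(self.clusters)}",
            f"blocks: {len(self.blocks)} "
            f"(SPLS eta={self.config.eta}, K={self.config.K})",
            "",
            "block      n_snps  n_genes  group_norm",
        ]
        norms = self.group_lasso.group_norms()
        for b in self.blocks:
            cid = b.gene_cluster.cluster_id
            lines.append(
                f"{b.block_id:<10} {len(b.snp_ids):>6} {len(b.gene_ids):>8} "
                f"{norms.get(cid, 0.0):>11.4f}"
            )
        top = self.pathway_scores(top_n=5)
        if len(top):
            lines += ["", "top pathways (snp -> gene, PS):"]
            for _, row in top.iterrows():
                lines.append(
                    f"  {row['rank']:>2}. {row['snp_id']} -> {row['gene_id']}  "
                    f"PS={row['ps']:.4f}"
                )
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Store the fitted ensemble (ids, coefficients, scalers) as JSON."""
        def ser_series(s: pd.Series):
            return {"index": list(map(str, s.index)), "values": [float(v) for v in s.to_numpy()]}

        payload = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "group_lasso": {
                "coefficients": ser_series(self.group_lasso.coefficients),
                "intercept": self.group_lasso.intercept,
                "lambda": self.group_lasso.lambda_,
                "groups": {k: list(v) for k, v in self.group_lasso.groups.items()},
                "selected": list(self.group_lasso.selected_clusters),
            },
            "blocks": [
                {
                    "block_id": m.block_id,
                    "snp_ids": list(m.spls.snp_ids),
                    "gene_ids": list(m.spls.gene_ids),
                    "eta": m.spls.eta,
                    "K": m.spls.K,
                    "n_components": m.spls.n_components,
                    "B": m.spls.coefficients.to_numpy().tolist(),
                    "x_mean": m.spls.x_mean.to_numpy().tolist(),
                    "x_scale": m.spls.x_scale.to_numpy().tolist(),
                    "y_mean_spls": m.spls.y_mean.to_numpy().tolist(),
                    "y_scale_spls": m.spls.y_scale.to_numpy().tolist(),
                    "logistic_coef": m.gene_logistic.coef.tolist(),
                    "logistic_intercept": m.gene_logistic.intercept,
                    "logistic_y_mean": m.gene_logistic.y_mean.tolist(),
                    "logistic_y_scale": m.gene_logistic.y_scale.tolist(),
                    "ridge": m.gene_logistic.ridge,
                }
                for m in self.block_models
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load_block_models(path) -> tuple[list, pd.Series]:
        """Reload block models and the group-lasso coefficient vector from a
        bundle written by :meth:`save` (enough for prediction and scoring)."""
        with open(path) as fh:
            payload = json.load(fh)
        models = []
        for blk in payload["blocks"]:
            spls = SPLSModel(
                eta=blk["eta"],
                K=blk["K"],
                n_components=blk["n_components"],
                coefficients=pd.DataFrame(
                    np.asarray(blk["B"]), index=blk["snp_ids"], columns=blk["gene_ids"]
                ),
                component_scores=np.zeros((0, 0)),
                x_mean=pd.Series(blk["x_mean"], index=blk["snp_ids"]),
                x_scale=pd.Series(blk["x_scale"], index=blk["snp_ids"]),
                y_mean=pd.Series(blk["y_mean_spls"], index=blk["gene_ids"]),
                y_scale=pd.Series(blk["y_scale_spls"], index=blk["gene_ids"]),
            )
            gl = GeneLogistic(
                gene_ids=blk["gene_ids"],
                coef=np.asarray(blk["logistic_coef"]),
                intercept=blk["logistic_intercept"],
                y_mean=np.asarray(blk["logistic_y_mean"]),
                y_scale=np.asarray(blk["logistic_y_scale"]),
                ridge=blk["ridge"],
            )
            models.append(BlockModel(blk["block_id"], spls, gl))
        gl_raw = payload["group_lasso"]["coefficients"]
        coef = pd.Series(gl_raw["values"], index=gl_raw["index"])
        return models, coef


@dataclass
class CVResults:
    """Out-of-fold predictions of the cross-validated block ensemble."""

    oof_probabilities: pd.Series
    phenotype: PhenotypeVector
    folds: list
    n_folds: int
    seed: int

    @property
    def auc(self) -> float:
        return self.roc().auc

    def roc(self) -> "evaluation.RocResult":
        return evaluation.roc_auc(self.oof_probabilities.to_numpy(), self.phenotype)

    def summary(self) -> str:
        return (
            f"{self.n_folds}-fold cross-validated block ensemble "
            f"(seed {self.seed}): pooled out-of-fold AUC = {self.auc:.3f} "
            f"on {len(self.oof_probabilities)} samples"
        )
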