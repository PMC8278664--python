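import numpy as np
import pandas as pd
import pytest

import omicblocks as ob
from omicblocks.blocks import Block
from omicblocks.model import (
    EmptySelectionError,
    average_predictions,
    fit_block,
    fit_gene_logistic,
    predict_block,
)
from omicblocks.network import GeneCluster
from omicblocks.preprocess import PhenotypeVector
from omicblocks.spls import SPLSModel


def _pheno(labels):
    return PhenotypeVector(pd.Series(labels, index=[f"s{i}" for i in range(len(labels))]))


def _frame(M, prefix):
    return pd.DataFrame(
        M,
        index=[f"s{i}" for i in range(M.shape[0])],
        columns=[f"{prefix}{j}" for j in range(M.shape[1])],
    )


class TestGeneLogistic:
    def test_perfect_single_gene_saturates_under_weak_ridge(self):
        n = 20
        y = np.array([0] * 10 + [1] * 10)
        Y = _frame((y * 2.0 - 1.0).reshape(-1, 1), "gene")
        gl = fit_gene_logistic(Y, _pheno(y), ridge=0.01)
        probs = gl.predict_proba(Y)
        assert (probs[y == 1] >= 0.99).all()
        assert (probs[y == 0] <= 0.01).all()

    def test_null_expression_gives_chance_level_training_auc(self):
        # n >> p so in-sample overfitting cannot lift the AUC off chance
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.array([0, 1] * 100)
            Y = _frame(rng.normal(size=(200, 2)), "gene")
            gl = fit_gene_logistic(Y, _pheno(y), ridge=1.0)
            aucs.append(ob.roc_auc(gl.predict_proba(Y), _pheno(y)).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_duplicated_gene_columns_stay_finite(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=30)
        Y = _frame(np.column_stack([col, col, col]), "gene")
        y = (col > 0).astype(int)
        gl = fit_gene_logistic(Y, _pheno(y))
        assert np.isfinite(gl.coef).all() and np.isfinite(gl.intercept)

    def test_single_class_rejected(self):
        Y = _frame(np.zeros((4, 2)), "gene")
        with pytest.raises(ValueError):
            fit_gene_logistic(Y, _pheno([1, 1, 1, 1]))


def _manual_block_model(B, x_cols, y_cols, coef, intercept=0.0):
    """BlockModel with hand-set coefficient matrices and identity scalers."""
    from omicblocks.model import BlockModel, GeneLogistic

    spls = SPLSModel(
        eta=0.0,
        K=1,
        n_components=1,
        coefficients=pd.DataFrame(B, index=x_cols, columns=y_cols),
        component_scores=np.zeros((0, 0)),
        x_mean=pd.Series(0.0, index=x_cols),
        x_scale=pd.Series(1.0, index=x_cols),
        y_mean=pd.Series(0.0, index=y_cols),
        y_scale=pd.Series(1.0, index=y_cols),
    )
    gl = GeneLogistic(
        gene_ids=list(y_cols),
        coef=np.asarray(coef, dtype=float),
        intercept=intercept,
        y_mean=np.zeros(len(y_cols)),
        y_scale=np.ones(len(y_cols)),
        ridge=0.01,
    )
    return BlockModel("B_manual", spls, gl)


class TestPredictBlock:
    def test_zero_coefficients_give_constant_probability(self):
        m = _manual_block_model(
            np.zeros((2, 2)), ["rs1", "rs2"], ["G1", "G2"], [1.0, -1.0], intercept=0.3
        )
        X = _frame(np.arange(10.0).reshape(5, 2), "rs").rename(
            columns={"rs0": "rs1", "rs1": "rs2"}
        )
        probs = predict_block(m, X)
        expected = 1 / (1 + np.exp(-0.3))
        np.testing.assert_allclose(probs, expected)

    def test_dosage_shift_moves_prediction_by_coefficient_row(self):
        rng = np.random.default_rng(2)
        X = _frame(rng.normal(size=(8, 3)), "snp")
        Y = _frame(rng.normal(size=(8, 2)), "gene")
        model = ob.fit_spls(X, Y, eta=0.0, K=2)
        X2 = X.copy()
        X2["snp1"] += 1.0
        delta = model.predict_expression(X2).to_numpy() - model.predict_expression(X).to_numpy()
        row = model.coefficients.loc["snp1"].to_numpy()
        expected = row * model.y_scale.to_numpy() / model.x_scale["snp1"]
        np.testing.assert_allclose(delta, np.tile(expected, (8, 1)), atol=1e-10)

    def test_missing_snp_columns_named_in_error(self):
        m = _manual_block_model(np.eye(2), ["rs1", "rs2"], ["G1", "G2"], [1.0, 0.0])
        X = _frame(np.zeros((3, 1)), "x").rename(columns={"x0": "rs1"})
        with pytest.raises(KeyError, match="rs2"):
            predict_block(m, X)


class TestAveragePredictions:
    def test_single_block_passthrough(self):
        v = np.array([0.2, 0.9])
        pred = average_predictions({"b1": v})
        np.testing.assert_array_equal(pred.final, v)

    def test_two_block_mean_and_permutation_invariance(self):
        a, b = np.array([0.4, 0.1]), np.array([0.6, 0.5])
        p1 = average_predictions({"a": a, "b": b})
        p2 = average_predictions({"b": b, "a": a})
        np.testing.assert_allclose(p1.final, [0.5, 0.3])
        np.testing.assert_allclose(p1.final, p2.final)

    def test_mean_bounded_by_blockwise_extremes(self):
        rng = np.random.default_rng(3)
        vecs = {f"b{i}": rng.uniform(size=12) for i in range(5)}
        pred = average_predictions(vecs)
        stacked = np.vstack(list(vecs.values()))
        assert (pred.final >= stacked.min(axis=0) - 1e-12).all()
        assert (pred.final <= stacked.max(axis=0) + 1e-12).all()

    def test_empty_and_ragged_inputs_rejected(self):
        with pytest.raises(ValueError):
            average_predictions({})
        with pytest.raises(ValueError):
            average_predictions({"a": [0.1], "b": [0.1, 0.2]})


class TestFitCv:
    def test_stratified_folds_balanced_at_n20(self, default_dataset):
        data, g = default_dataset
        ids = ob.evaluation.balanced_subsample(data.phenotype, 20, np.random.default_rng(0))
        model = ob.BlockEnsemble(
            g.restrict(samples=ids),
            data.expression.restrict(samples=ids),
            data.phenotype.restrict(ids),
            data.ppi_edges,
            data.eqtl,
        )
        cv = model.fit_cv(n_folds=5, seed=0)
        y = model.phenotype.values
        for _, te in cv.folds:
            assert len(te) == 4
            assert y[te].sum() == 2  # 2 cases + 2 controls held out

    def test_full_fit_and_prediction_shapes(self, default_dataset):
        data, g = default_dataset
        model = ob.BlockEnsemble(g, data.expression, data.phenotype, data.ppi_edges, data.eqtl)
        res = model.fit(seed=0)
        pred = res.predict(model.genotypes)
        assert len(pred.final) == len(model.phenotype.samples)
        assert ((pred.final >= 0) & (pred.final <= 1)).all()
        assert len(res.pathway_scores(top_n=10)) <= 10
        assert "Block-ensemble" in res.summary()
        # every block's SNPs come from the QC-passed panel
        panel = set(model.genotypes.snps)
        for b in res.blocks:
            assert set(b.snp_ids) <= panel

    def test_model_bundle_roundtrip(self, default_dataset, tmp_path):
        data, g = default_dataset
        model = ob.BlockEnsemble(g, data.expression, data.phenotype, data.ppi_edges, data.eqtl)
        res = model.fit(seed=0)
        path = tmp_path / "bundle.json"
        res.save(path)
        models, gl_coef = ob.BlockEnsembleResults.load_block_models(path)
        reloaded = average_predictions(
            {m.block_id: predict_block(m, model.genotypes.data) for m in models}
        )
        np.testing.assert_allclose(
            reloaded.final, res.predict(model.genotypes).final, atol=1e-12
        )

    def test_screening_dead_end_raises_on_direct_fit(self, default_dataset):
        data, g = default_dataset
        rng = np.random.default_rng(123)
        perm = PhenotypeVector(
            pd.Series(rng.permutation(data.phenotype.labels.to_numpy()),
                      index=data.phenotype.samples)
        )
        # a huge fixed penalty guarantees an empty selection
        cfg = ob.PipelineConfig(lambda_=10.0)
        model = ob.BlockEnsemble(g, data.expression, perm, data.ppi_edges, data.eqtl, config=cfg)
        with pytest.raises(EmptySelectionError):
            model.fit(seed=0)
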