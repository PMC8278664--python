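import numpy as np
import pandas as pd
import pytest

from omicblocks.grouplasso import (
    fit_group_lasso,
    kkt_violation,
    lambda_max,
    lambda_path,
    screen_clusters,
    select_lambda,
)
from omicblocks.network import GeneCluster
from omicblocks.preprocess import ExpressionMatrix, PhenotypeVector


def make_problem(n=100, n_clusters=5, genes_per_cluster=2, signal=1.0, seed=0):
    """Logistic data where the first cluster's genes carry the signal."""
    rng = np.random.default_rng(seed)
    p = n_clusters * genes_per_cluster
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:genes_per_cluster] = signal
    prob = 1 / (1 + np.exp(-(X @ beta)))
    y = (rng.uniform(size=n) < prob).astype(int)
    genes = [f"g{j:02d}" for j in range(p)]
    samples = [f"s{i:03d}" for i in range(n)]
    e = ExpressionMatrix(pd.DataFrame(X, index=samples, columns=genes))
    clusters = [
        GeneCluster(
            f"c{k}", frozenset(genes[k * genes_per_cluster : (k + 1) * genes_per_cluster]), 0.5
        )
        for k in range(n_clusters)
    ]
    pheno = PhenotypeVector(pd.Series(y, index=samples))
    return e, clusters, pheno


class TestSolverAgainstMLE:
    def test_unpenalized_fit_matches_irls_oracle(self):
        """At lambda=0 the solver is plain logistic regression; statsmodels'
        Newton/IRLS solver is the independent oracle."""
        import statsmodels.api as sm

        e, clusters, pheno = make_problem(n=100, n_clusters=5, genes_per_cluster=2)
        fit = fit_group_lasso(e, clusters, pheno, 0.0, tol=1e-12, max_iter=50_000)
        X = e.data.to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        ref = sm.Logit(pheno.values, sm.add_constant(Z)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-4)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), ref.params[1:], atol=1e-4
        )

    def test_full_shrinkage_above_lambda_max(self):
        e, clusters, pheno = make_problem()
        lam = 1.01 * lambda_max(e, clusters, pheno)
        fit = fit_group_lasso(e, clusters, pheno, lam)
        assert (fit.coefficients == 0.0).all()
        assert fit.selected_clusters == ()
        ybar = pheno.values.mean()
        assert fit.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)


class TestKktAndPathProperties:
    def test_kkt_certificate_along_path(self):
        e, clusters, pheno = make_problem()
        path = lambda_path(lambda_max(e, clusters, pheno), n_lambda=10, min_ratio=0.05)
        fit = None
        for lam in path:
            fit = fit_group_lasso(
                e, clusters, pheno, lam, tol=1e-10, max_iter=30_000, warm_start=fit
            )
            assert kkt_violation(fit, e, clusters, pheno) <= 1e-4

    def test_selected_count_monotone_in_lambda(self):
        e, clusters, pheno = make_problem(signal=0.8, seed=3)
        path = lambda_path(lambda_max(e, clusters, pheno), n_lambda=12, min_ratio=0.02)
        counts = []
        fit = None
        for lam in path:  # descending
            fit = fit_group_lasso(e, clusters, pheno, lam, warm_start=fit,
                                  raise_on_fail=False)
            counts.append(len(fit.selected_clusters))
        assert counts == sorted(counts)

    def test_objective_history_non_increasing(self):
        e, clusters, pheno = make_problem()
        lam = 0.3 * lambda_max(e, clusters, pheno)
        fit = fit_group_lasso(e, clusters, pheno, lam)
        hist = fit.objective_history
        assert np.all(np.diff(hist) <= 1e-12)


class TestSelectLambda:
    def test_single_candidate_returned(self):
        e, clusters, pheno = make_problem()
        lam = select_lambda(e, clusters, pheno, n_lambda=1)
        assert lam == pytest.approx(lambda_max(e, clusters, pheno))

    def test_permuted_labels_give_sparse_model(self):
        e, clusters, pheno = make_problem(n=80, seed=1)
        rng = np.random.default_rng(5)
        perm = PhenotypeVector(
            pd.Series(rng.permutation(pheno.labels.to_numpy()), index=pheno.samples)
        )
        lam = select_lambda(e, clusters, perm, seed=2)
        fit = fit_group_lasso(e, clusters, perm, lam, raise_on_fail=False)
        assert len(fit.selected_clusters) <= 2

    def test_signal_beats_null_model_on_heldout_auc(self):
        e, clusters, pheno = make_problem(n=120, signal=1.5, seed=4)
        lam, table = select_lambda(e, clusters, pheno, seed=0, return_path=True)
        auc_at_best = table.loc[table["lambda"] == lam, "mean_auc"].iloc[0]
        auc_at_max = table["mean_auc"].iloc[0]  # lambda_max: all-zero model
        assert auc_at_best > auc_at_max
        assert lam < table["lambda"].iloc[0]


class TestScreenClusters:
    def test_zero_fit_selects_nothing_and_single_block_selects_one(self):
        e, clusters, pheno = make_problem(signal=2.0, seed=6)
        lam_hi = 1.1 * lambda_max(e, clusters, pheno)
        assert screen_clusters(fit_group_lasso(e, clusters, pheno, lam_hi), clusters) == []

        lam = 0.6 * lambda_max(e, clusters, pheno)
        fit = fit_group_lasso(e, clusters, pheno, lam)
        selected = screen_clusters(fit, clusters)
        # independent recomputation from the coefficient vector
        expected = [
            c.cluster_id
            for c in clusters
            if np.linalg.norm(fit.coefficients[sorted(c.genes)].to_numpy()) > 1e-10
        ]
        assert [c.cluster_id for c in selected] == expected
        assert expected  # the strong planted cluster is picked up

    def test_overlapping_clusters_rejected(self):
        e, clusters, pheno = make_problem()
        bad = clusters + [GeneCluster("dup", clusters[0].genes, 0.5)]
        with pytest.raises(ValueError, match="disjoint"):
            fit_group_lasso(e, bad, pheno, 0.1)
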