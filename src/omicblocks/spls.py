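"""Sparse partial least squares (SPLS) linking SNP dosages to gene expression.

PLS extracts paired latent components from the genotype matrix X (n x p) and
expression matrix Y (n x q) so that each component pair carries maximal
cross-covariance; regression on the components handles p >> n and strong
collinearity. SPLS adds an L1-style sparsification: per component the
direction vector (dominant left singular vector of the current
cross-covariance X' Y_residual) is soft-thresholded at a fraction ``eta`` of
its largest absolute entry, the surviving SNPs join the active set, a dense
PLS with the components so far is refit on the active SNPs only, and the
response residual is deflated. At ``eta = 0`` nothing is thresholded and the
result is exactly the dense PLS solution; as ``eta`` approaches 1 only the
single strongest SNP survives per component.

The returned coefficient matrix B (SNPs x genes) lives on the standardized
scale; centering/scaling parameters are stored so prediction reproduces the
training transform. Dense PLS refits use scikit-learn's NIPALS
implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

logger = logging.getLogger(__name__)


@dataclass
class SPLSModel:
    """Sparse SNP -> gene coefficient matrix with fitted components."""

    eta: float
    K: int
    n_components: int
    coefficients: pd.DataFrame  # snps x genes, standardized scale
    component_scores: np.ndarray  # n x n_components latent t-scores
    x_mean: pd.Series
    x_scale: pd.Series
    y_mean: pd.Series
    y_scale: pd.Series

    @property
    def snp_ids(self) -> list[str]:
        return list(self.coefficients.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coefficients.columns)

    @property
    def active_snps(self) -> tuple:
        B = self.coefficients.to_numpy()
        mask = np.any(B != 0.0, axis=1)
        return tuple(np.asarray(self.coefficients.index)[mask])

    def predict_expression(self, X_new: pd.DataFrame) -> pd.DataFrame:
        """Map new SNP dosages to expression on the raw (training) scale."""
        missing = [s for s in self.snp_ids if s not in X_new.columns]
        if missing:
            raise KeyError(f"missing SNP columns: {missing[:10]}")
        Z = (X_new[self.snp_ids] - self.x_mean) / self.x_scale
        Yhat = Z.to_numpy(dtype=float) @ self.coefficients.to_numpy()
        Yhat = Yhat * self.y_scale.to_numpy() + self.y_mean.to_numpy()
        return pd.DataFrame(Yhat, index=X_new.index, columns=self.gene_ids)


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    scale = M.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return (M - mean) / scale, mean, scale


def _direction(M: np.ndarray) -> np.ndarray:
    """Dominant left singular vector of the cross-covariance, sign-fixed so
    its largest-magnitude entry is positive (determinism)."""
    if M.shape[1] == 1:
        w = M[:, 0].copy()
    else:
        u, _, _ = np.linalg.svd(M, full_matrices=False)
        w = u[:, 0]
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


def _soft_threshold(w: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(w) * np.maximum(np.abs(w) - thresh, 0.0)


def fit_spls(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    eta: float = 0.5,
    K: int = 2,
) -> SPLSModel:
    """Fit the sparse SNP -> gene regression.

    Parameters
    ----------
    X, Y : DataFrames with identical sample index (samples x SNPs / genes).
    eta : sparsity in [0, 1); fraction of the largest direction entry below
        which entries are thresholded away.
    K : number of latent components (clipped to the rank bound with a log).
    """
    if not 0.0 <= eta < 1.0:
        raise ValueError("eta must be in [0, 1)")
    if K < 1:
        raise ValueError("K must be >= 1")
    if not X.index.equals(Y.index):
        raise ValueError("X and Y sample indices differ")
    n, p = X.shape
    q = Y.shape[1]
    Xc, x_mean, x_scale = _standardize(X.to_numpy(dtype=float))
    Yc, y_mean, y_scale = _standardize(Y.to_numpy(dtype=float))

    k_max = min(K, n - 1, p)
    if k_max < K:
        logger.info("fit_spls: K clipped from %d to rank bound %d", K, k_max)

    active = np.zeros(p, dtype=bool)
    B = np.zeros((p, q))
    scores = np.zeros((n, 0))
    n_comp = 0
    for k in range(1, k_max + 1):
        M = Xc.T @ (Yc - Xc @ B)  # cross-covariance with the response residual
        if np.max(np.abs(M)) < 1e-12 * n:
            if k == 1:
                warnings.warn(
                    "fit_spls: zero cross-covariance between X and Y; "
                    "returning an all-zero model",
                    stacklevel=2,
                )
            break
        w = _direction(M)
        w_thr = _soft_threshold(w, eta * np.max(np.abs(w)))
        active |= w_thr != 0.0
        k_eff = min(k, int(active.sum()), n - 1)
        # tight inner tolerance so the refit is NIPALS to numerical precision
        pls = PLSRegression(n_components=k_eff, scale=False, tol=1e-14, max_iter=10_000)
        pls.fit(Xc[:, active], Yc)
        B = np.zeros((p, q))
        B[active] = pls.coef_.T
        scores = pls.x_scores_
        n_comp = k_eff
    coefficients = pd.DataFrame(B, index=X.columns, columns=Y.columns)
    return SPLSModel(
        eta=eta,
        K=K,
        n_components=n_comp,
        coefficients=coefficients,
        component_scores=scores,
        x_mean=pd.Series(x_mean, index=X.columns),
        x_scale=pd.Series(x_scale, index=X.columns),
        y_mean=pd.Series(y_mean, index=Y.columns),
        y_scale=pd.Series(y_scale, index=Y.columns),
    )


def select_spls_params(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    etas=(0.1, 0.3, 0.5, 0.7, 0.9),
    Ks=(1, 2, 3),
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, int]:
    """Pick (eta, K) minimizing cross-validated mean squared prediction error
    of the expression from the genotypes. Ties break toward sparser (larger
    eta, smaller K)."""
    from sklearn.model_selection import KFold

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    best: tuple[float, float, int] | None = None
    for eta in sorted(etas, reverse=True):
        for K in sorted(Ks):
            mse = 0.0
            for tr, te in kf.split(X):
                m = fit_spls(X.iloc[tr], Y.iloc[tr], eta=eta, K=K)
                resid = m.predict_expression(X.iloc[te]).to_numpy() - Y.iloc[te].to_numpy()
                mse += float(np.mean(resid**2))
            mse /= n_folds
            if best is None or mse < best[0] - 1e-12:
                best = (mse, eta, K)
    assert best is not None
    logger.info("select_spls_params: eta=%.2f K=%d (cv mse %.4f)", best[1], best[2], best[0])
    return best[1], best[2]
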