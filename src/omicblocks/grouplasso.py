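"""Group-lasso-penalized logistic regression for gene-cluster screening.

Gene clusters act as feature groups: the model minimizes

    (1/n) sum_i log(1 + exp(eta_i)) - y_i eta_i
        + lambda * sum_g sqrt(p_g) * ||beta_g||_2

where eta = X beta + b, p_g is the number of genes in cluster g and the
intercept b is unpenalized. The sqrt(p_g) weights compensate for unequal
cluster sizes. The group penalty zeroes whole clusters, so clusters with a
nonzero coefficient block are the ones screened in as disease-relevant.

The solver is a monotone accelerated proximal-gradient method (FISTA with
the monotone modification and backtracking line search); the proximal step
is block soft-thresholding, so inactive groups are exactly zero. Expression
features are standardized internally (zero mean, unit variance) and
coefficients are reported on the standardized scale.

``lambda_max`` is the smallest penalty at which every group is zero;
``select_lambda`` walks a descending logarithmic path from it and picks the
penalty maximizing stratified cross-validated AUC (ties break toward the
larger, sparser penalty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .network import GeneCluster
from .preprocess import ExpressionMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

_SELECT_TOL = 1e-10  # group norms above this count as selected


class ConvergenceError(RuntimeError):
    """Raised when the proximal-gradient solver hits its iteration cap."""


@dataclass
class GroupLassoFit:
    """Converged group-lasso logistic fit on standardized expression."""

    coefficients: pd.Series  # per gene, standardized scale
    intercept: float
    lambda_: float
    groups: dict  # cluster_id -> list of gene ids (fit order)
    selected_clusters: tuple
    n_iter: int
    converged: bool
    objective: float
    x_mean: pd.Series
    x_scale: pd.Series
    objective_history: np.ndarray = field(repr=False, default=None)

    def group_norms(self) -> pd.Series:
        beta = self.coefficients
        return pd.Series(
            {
                cid: float(np.linalg.norm(beta[genes].to_numpy()))
                for cid, genes in self.groups.items()
            }
        )

    def decision_function(self, e: ExpressionMatrix) -> np.ndarray:
        genes = list(self.coefficients.index)
        Z = (e.data[genes] - self.x_mean[genes]) / self.x_scale[genes]
        return Z.to_numpy() @ self.coefficients.to_numpy() + self.intercept


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return (X - mean) / scale, mean, scale


def _nll(eta: np.ndarray, y: np.ndarray) -> float:
    # mean logistic negative log-likelihood, numerically stable
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _penalty(beta: np.ndarray, groups_idx, weights, lam: float) -> float:
    return lam * float(
        sum(w * np.linalg.norm(beta[idx]) for idx, w in zip(groups_idx, weights))
    )


def _prox(beta: np.ndarray, groups_idx, weights, thresh: float) -> np.ndarray:
    out = beta.copy()
    for idx, w in zip(groups_idx, weights):
        norm = np.linalg.norm(out[idx])
        t = thresh * w
        if norm <= t:
            out[idx] = 0.0
        else:
            out[idx] *= 1.0 - t / norm
    return out


def _fista(
    X: np.ndarray,
    y: np.ndarray,
    groups_idx,
    weights,
    lam: float,
    tol: float,
    max_iter: int,
    beta0: np.ndarray | None = None,
    intercept0: float | None = None,
):
    """Monotone FISTA with backtracking; returns (beta, b, history, converged)."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    ybar = y.mean()
    b = float(np.log(ybar / (1.0 - ybar))) if intercept0 is None else intercept0

    def smooth(bb, ib):
        return _nll(X @ bb + ib, y)

    def grad(bb, ib):
        r = _sigmoid(X @ bb + ib) - y
        return X.T @ r / n, float(r.mean())

    def full_obj(bb, ib):
        return smooth(bb, ib) + _penalty(bb, groups_idx, weights, lam)

    # Lipschitz estimate for the smooth part (logistic curvature <= 1/4)
    L = max(np.linalg.norm(np.hstack([np.ones((n, 1)), X]), 2) ** 2 / (4.0 * n), 1e-12)

    xb, xi = beta, b  # accepted iterate
    yb, yi = beta.copy(), b  # extrapolated point
    t_k = 1.0
    F = full_obj(xb, xi)
    history = [F]
    converged = False
    for _ in range(max_iter):
        g_beta, g_int = grad(yb, yi)
        f_y = smooth(yb, yi)
        while True:
            step = 1.0 / L
            zb = _prox(yb - step * g_beta, groups_idx, weights, lam * step)
            zi = yi - step * g_int
            diff_b, diff_i = zb - yb, zi - yi
            quad = (
                f_y
                + g_beta @ diff_b
                + g_int * diff_i
                + 0.5 * L * (diff_b @ diff_b + diff_i * diff_i)
            )
            if smooth(zb, zi) <= quad + 1e-12:
                break
            L *= 2.0
        Fz = full_obj(zb, zi)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        accepted = Fz <= F + 1e-15 * max(1.0, abs(F))
        if accepted:
            new_xb, new_xi, F_new = zb, zi, min(Fz, F)
        else:  # monotone modification: keep the best iterate
            new_xb, new_xi, F_new = xb, xi, F
        yb = new_xb + (t_k / t_next) * (zb - new_xb) + ((t_k - 1.0) / t_next) * (
            new_xb - xb
        )
        yi = new_xi + (t_k / t_next) * (zi - new_xi) + ((t_k - 1.0) / t_next) * (
            new_xi - xi
        )
        rel = abs(F - F_new) / max(1.0, abs(F_new))
        xb, xi, F = new_xb, new_xi, F_new
        t_k = t_next
        history.append(F)
        if accepted and rel < tol:
            converged = True
            break
        if not accepted:  # restart momentum after a rejected step
            yb, yi, t_k = xb.copy(), xi, 1.0
    return xb, xi, np.asarray(history), converged


def _group_layout(clusters: list[GeneCluster], genes: set):
    """Fit-order gene list and per-group index arrays (clusters must be
    disjoint; genes absent from the expression matrix are dropped)."""
    groups: dict[str, list[str]] = {}
    ordered: list[str] = []
    seen: set = set()
    for c in clusters:
        members = [g for g in c.sorted_genes() if g in genes]
        if not members:
            continue
        overlap = seen.intersection(members)
        if overlap:
            raise ValueError(f"clusters are not disjoint: {sorted(overlap)[:5]}")
        groups[c.cluster_id] = members
        ordered.extend(members)
        seen.update(members)
    if not ordered:
        raise ValueError("no cluster gene is present in the expression matrix")
    pos = {g: i for i, g in enumerate(ordered)}
    groups_idx = [np.array([pos[g] for g in members]) for members in groups.values()]
    weights = np.sqrt([len(members) for members in groups.values()])
    return ordered, groups, groups_idx, weights


def lambda_max(
    e: ExpressionMatrix, clusters: list[GeneCluster], p: PhenotypeVector
) -> float:
    """Smallest penalty for which every coefficient block is zero."""
    ordered, _, groups_idx, weights = _group_layout(clusters, set(e.genes))
    X, _, _ = _standardize(e.data[ordered].to_numpy(dtype=float))
    y = p.values
    g = X.T @ (y.mean() - y) / len(y)
    return max(
        float(np.linalg.norm(g[idx]) / w) for idx, w in zip(groups_idx, weights)
    )


def fit_group_lasso(
    e: ExpressionMatrix,
    clusters: list[GeneCluster],
    p: PhenotypeVector,
    lambda_: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    raise_on_fail: bool = True,
    warm_start: GroupLassoFit | None = None,
) -> GroupLassoFit:
    """Fit the group-lasso logistic model at a fixed penalty ``lambda_``."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    if not p.has_both_classes():
        raise ValueError("both phenotype classes must be present")
    if e.samples != p.samples:
        raise ValueError("expression and phenotype samples are not aligned")
    ordered, groups, groups_idx, weights = _group_layout(clusters, set(e.genes))
    raw = e.data[ordered].to_numpy(dtype=float)
    X, mean, scale = _standardize(raw)
    y = p.values

    beta0 = intercept0 = None
    if warm_start is not None and list(warm_start.coefficients.index) == ordered:
        beta0 = warm_start.coefficients.to_numpy().copy()
        intercept0 = warm_start.intercept
    beta, b, history, converged = _fista(
        X, y, groups_idx, weights, lambda_, tol, max_iter, beta0, intercept0
    )
    if not converged:
        msg = f"group lasso did not converge in {max_iter} iterations (lambda={lambda_:.4g})"
        if raise_on_fail:
            raise ConvergenceError(msg)
        logger.warning(msg)

    series = pd.Series(beta, index=ordered)
    selected = tuple(
        cid
        for cid, idx in zip(groups.keys(), groups_idx)
        if np.linalg.norm(beta[idx]) > _SELECT_TOL
    )
    return GroupLassoFit(
        coefficients=series,
        intercept=float(b),
        lambda_=float(lambda_),
        groups=groups,
        selected_clusters=selected,
        n_iter=len(history) - 1,
        converged=converged,
        objective=float(history[-1]),
        x_mean=pd.Series(mean, index=ordered),
        x_scale=pd.Series(scale, index=ordered),
        objective_history=history,
    )


def lambda_path(lam_max: float, n_lambda: int = 10, min_ratio: float = 0.05) -> np.ndarray:
    """Descending logarithmic penalty path from ``lam_max``."""
    if n_lambda == 1:
        return np.array([lam_max])
    return lam_max * np.logspace(0.0, np.log10(min_ratio), n_lambda)


def select_lambda(
    e: ExpressionMatrix,
    clusters: list[GeneCluster],
    p: PhenotypeVector,
    n_folds: int = 3,
    n_lambda: int = 10,
    min_ratio: float = 0.05,
    seed: int = 0,
    max_iter: int = 2_000,
    tol: float = 1e-7,
    return_path: bool = False,
):
    """Choose the penalty maximizing mean held-out AUC over stratified folds.

    Ties break toward the larger penalty (the sparser model). Path fits are
    warm-started down the path with a relaxed iteration cap; non-convergence
    there is a logged diagnostic, not an error.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    path = lambda_path(lambda_max(e, clusters, p), n_lambda, min_ratio)
    y = p.values
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = np.zeros((n_folds, len(path)))
    for k, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        samples = np.asarray(p.samples)
        e_tr = e.restrict(samples=samples[tr])
        p_tr = p.restrict(samples[tr])
        e_te = e.restrict(samples=samples[te])
        if not (p_tr.has_both_classes() and len(set(y[te])) == 2):
            raise ValueError("degenerate (single-class) cross-validation fold")
        fit = None
        for j, lam in enumerate(path):
            fit = fit_group_lasso(
                e_tr, clusters, p_tr, lam,
                tol=tol, max_iter=max_iter, raise_on_fail=False, warm_start=fit,
            )
            scores = fit.decision_function(e_te)
            if np.ptp(scores) == 0.0:
                aucs[k, j] = 0.5
            else:
                aucs[k, j] = roc_auc_score(y[te], scores)
    mean_auc = aucs.mean(axis=0)
    best = int(np.argmax(mean_auc))  # first max -> largest lambda
    logger.info(
        "select_lambda: lambda=%.4g (mean held-out AUC %.3f)", path[best], mean_auc[best]
    )
    if return_path:
        table = pd.DataFrame({"lambda": path, "mean_auc": mean_auc})
        return float(path[best]), table
    return float(path[best])


def screen_clusters(
    fit: GroupLassoFit, clusters: list[GeneCluster]
) -> list[GeneCluster]:
    """Clusters whose coefficient-block norm is nonzero, in input order."""
    selected = [c for c in clusters if c.cluster_id in fit.selected_clusters]
    if not selected:
        logger.warning("screen_clusters: no cluster selected at lambda=%.4g", fit.lambda_)
    return selected


def kkt_violation(
    fit: GroupLassoFit,
    e: ExpressionMatrix,
    clusters: list[GeneCluster],
    p: PhenotypeVector,
) -> float:
    """Maximum violation of the stationarity conditions at the fitted point.

    For an inactive group the gradient-block norm must not exceed
    lambda*sqrt(p_g); for an active group the gradient must cancel the
    penalty subgradient. Returns the largest absolute violation.
    """
    ordered, groups, groups_idx, weights = _group_layout(clusters, set(e.genes))
    X, _, _ = _standardize(e.data[ordered].to_numpy(dtype=float))
    y = p.values
    beta = fit.coefficients[ordered].to_numpy()
    r = _sigmoid(X @ beta + fit.intercept) - y
    g = X.T @ r / len(y)
    viol = abs(float(r.mean()))  # intercept stationarity
    for idx, w in zip(groups_idx, weights):
        bn = np.linalg.norm(beta[idx])
        if bn <= _SELECT_TOL:
            viol = max(viol, float(np.linalg.norm(g[idx])) - fit.lambda_ * w)
        else:
            stat = g[idx] + fit.lambda_ * w * beta[idx] / bn
            viol = max(viol, float(np.linalg.norm(stat)))
    return viol
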