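"""ROC/AUC evaluation and the sample-size experiment harness.

Classification is binary and thresholds are never fixed: performance is the
full ROC curve and its area. Tied scores follow the Mann-Whitney
convention (ties count one half), which the trapezoidal area over the
threshold-swept curve reproduces exactly.

The sample-size experiment repeatedly draws balanced subsamples of a
dataset at decreasing n, reruns the full cross-validated pipeline and
records the AUC. Sizes below 20 are rejected: with fewer than 20 samples
the group-lasso screening stage cannot achieve an effective regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .preprocess import ExpressionMatrix, GenotypeMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

MIN_SAMPLE_SIZE = 20


@dataclass(frozen=True)
class RocResult:
    """ROC points (fpr, tpr) from (0,0) to (1,1) and the trapezoidal area."""

    points: np.ndarray  # (k, 2) array of (fpr, tpr)
    auc: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve by threshold sweep and AUC by the trapezoid rule."""
    y = labels.values if isinstance(labels, PhenotypeVector) else np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    if len(set(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    if np.ptp(s) == 0.0:
        # all scores tied: the ROC is the diagonal
        points = np.array([[0.0, 0.0], [1.0, 1.0]])
        return RocResult(points=points, auc=0.5)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return RocResult(points=points, auc=float(np.trapezoid(tpr, fpr)))


def balanced_subsample(
    p: PhenotypeVector, n: int, rng: np.random.Generator
) -> list[str]:
    """Sample ids for a balanced subsample of size ``n`` (n/2 per class);
    requesting the full dataset size returns every sample."""
    samples = np.asarray(p.samples)
    if n == len(samples):
        return list(samples)
    if n % 2:
        raise ValueError("subsample size must be even (balanced classes)")
    y = p.values
    cases, controls = samples[y == 1], samples[y == 0]
    half = n // 2
    if half > len(cases) or half > len(controls):
        raise ValueError(f"cannot draw {half} per class from {len(cases)}/{len(controls)}")
    picked = np.concatenate(
        [rng.choice(cases, half, replace=False), rng.choice(controls, half, replace=False)]
    )
    return sorted(picked)


def sample_size_experiment(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    phenotype: PhenotypeVector,
    ppi_edges,
    eqtl,
    sizes,
    seeds,
    n_folds: int = 5,
    config=None,
    return_runs: bool = False,
):
    """AUC of the cross-validated pipeline on balanced subsamples.

    For each n in ``sizes`` and each seed, a balanced subsample is drawn,
    the full pipeline is cross-validated on it and the pooled out-of-fold
    AUC recorded. Returns a table of (n, mean_auc, sd_auc); with
    ``return_runs`` also the per-run table.
    """
    from .model import BlockEnsemble

    sizes = list(sizes)
    for n in sizes:
        if n < MIN_SAMPLE_SIZE:
            raise ValueError(
                f"sample size {n} rejected: below {MIN_SAMPLE_SIZE} the group-lasso "
                "screening cannot achieve effective regression"
            )
        if n % 2:
            raise ValueError("sizes must be even for balanced subsampling")
    runs = []
    for n in sizes:
        for seed in seeds:
            rng = np.random.default_rng(seed)
            ids = balanced_subsample(phenotype, n, rng)
            model = BlockEnsemble(
                genotypes.restrict(samples=ids),
                expression.restrict(samples=ids),
                phenotype.restrict(ids),
                ppi_edges,
                eqtl,
                config=config,
            )
            auc = model.fit_cv(n_folds=n_folds, seed=int(seed)).auc
            runs.append({"n": n, "seed": int(seed), "auc": auc})
            logger.info("sample_size_experiment: n=%d seed=%d auc=%.3f", n, seed, auc)
    runs_df = pd.DataFrame(runs)
    summary = (
        runs_df.groupby("n", sort=False)["auc"]
        .agg(mean_auc="mean", sd_auc="std")
        .reset_index()
    )
    if return_runs:
        return summary, runs_df
    return summary
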