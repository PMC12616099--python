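"""Ridge regression head on frozen embeddings, MAE and multi-seed aggregation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .contrastive import EmbeddingMatrix

__all__ = ["RidgeModel", "RunAggregate", "fit_ridge", "fit_ridge_cv",
           "predict_age", "evaluate_mae", "aggregate_runs"]


@dataclass
class RidgeModel:
    weights: np.ndarray
    intercept: float
    lam: float
    feature_mean: np.ndarray
    target_mean: float


@dataclass
class RunAggregate:
    """MAE across repeated runs with a t-distribution 95% CI."""

    per_seed_mae: np.ndarray
    mean_mae: float
    ci95: tuple[float, float]


def _as_matrix(emb: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    return emb.vectors if isinstance(emb, EmbeddingMatrix) else np.asarray(emb, float)


def fit_ridge(emb: EmbeddingMatrix | np.ndarray, ages: np.ndarray,
              lam: float = 1.0) -> RidgeModel:
    """Closed-form ridge on mean-centred features and targets.

    w = (X^T X + lam I)^{-1} X^T y with X, y centred; the intercept restores
    the means so that predictions are on the age scale.
    """
    X = _as_matrix(emb)
    y = np.asarray(ages, dtype=np.float64)
    if X.shape[0] != y.size or X.shape[0] < 2:
        raise ValueError("need n > 1 matched samples")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    fmean = X.mean(axis=0)
    tmean = float(y.mean())
    Xc = X - fmean
    yc = y - tmean
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    if lam == 0 and np.linalg.matrix_rank(A) < X.shape[1]:
        raise np.linalg.LinAlgError("singular system at lam=0 (collinear features)")
    w = np.linalg.solve(A, Xc.T @ yc)
    return RidgeModel(weights=w, intercept=tmean, lam=lam,
                      feature_mean=fmean, target_mean=tmean)


def fit_ridge_cv(emb: EmbeddingMatrix | np.ndarray, ages: np.ndarray,
                 lambdas: Sequence[float] = tuple(10.0 ** np.arange(-3, 4.0)),
                 n_folds: int = 5, seed: int = 0) -> tuple[RidgeModel, float]:
    """Inner k-fold CV over a log grid of penalties; returns (model, best lam)."""
    X = _as_matrix(emb)
    y = np.asarray(ages, dtype=np.float64)
    n = y.size
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    best_lam, best_err = None, np.inf
    for lam in lambdas:
        errs = []
        for f in folds:
            tr = np.setdiff1d(np.arange(n), f)
            m = fit_ridge(X[tr], y[tr], lam)
            errs.append(evaluate_mae(predict_age(m, X[f]), y[f]))
        err = float(np.mean(errs))
        if err < best_err:
            best_lam, best_err = lam, err
    model = fit_ridge(X, y, best_lam)
    return model, float(best_lam)


def predict_age(model: RidgeModel, emb: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    X = _as_matrix(emb)
    if X.shape[1] != model.weights.size:
        raise ValueError("embedding dimension does not match model")
    return (X - model.feature_mean) @ model.weights + model.target_mean


def evaluate_mae(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("prediction and truth must be equal-length, nonempty")
    return float(np.mean(np.abs(pred - truth)))


def aggregate_runs(per_seed_mae: Sequence[float]) -> RunAggregate:
    """Mean MAE with a 95% CI from the t-distribution over runs."""
    vals = np.asarray(per_seed_mae, dtype=np.float64)
    n = vals.size
    if n < 2:
        raise ValueError("need at least 2 runs to aggregate")
    mean = float(vals.mean())
    sem = vals.std(ddof=1) / np.sqrt(n)
    half = float(stats.t.ppf(0.975, n - 1) * sem)
    return RunAggregate(per_seed_mae=vals, mean_mae=mean,
                        ci95=(mean - half, mean + half))
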