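"""Model validation: metrics, k-fold machinery, bootstrap bias-corrected
cross-validation (BBC-CV), learning curves, and grouped leave-one-out.

BBC-CV builds one shared out-of-fold prediction matrix for all candidate
configurations, then bootstraps sample indices of that matrix: each resample
selects the configuration with lowest MAE on the resampled rows and scores it
on the out-of-bag rows.  The mean out-of-bag score is an estimate of the
winner's generalization error that accounts for the optimism of selection.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from . import model_zoo
from .model_zoo import ModelConfig


@dataclass
class MetricReport:
    r2: float
    mae: float
    rmse: float
    n: int
    mae_se: float | None = None
    rmse_se: float | None = None
    r2_se: float | None = None
    r2_cod: float | None = None  # coefficient-of-determination variant

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "mae": self.mae,
            "rmse": self.rmse,
            "n": self.n,
            "mae_se": self.mae_se,
            "rmse_se": self.rmse_se,
            "r2_cod": self.r2_cod,
        }


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricReport:
    """R^2 (squared Pearson correlation), MAE and RMSE.

    The standard error attached to the MAE is the SEM of the absolute
    residuals; RMSE/R^2 standard errors are left to fold- or bootstrap-based
    estimation (see :func:`bootstrap_se`).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise ValueError("non-finite values in inputs")
    n = y_true.size
    if n < 1:
        raise ValueError("need n >= 1")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if n >= 2 and np.std(y_true) > 0 and np.std(y_pred) > 0:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
        r2 = r * r
        ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
        r2_cod = 1.0 - float(np.sum(err**2)) / ss_tot
    else:
        r2 = float("nan")
        r2_cod = float("nan")
    mae_se = float(np.std(np.abs(err), ddof=1) / np.sqrt(n)) if n >= 2 else None
    return MetricReport(r2=r2, mae=mae, rmse=rmse, n=n, mae_se=mae_se, r2_cod=r2_cod)


def bootstrap_se(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """Metrics with bootstrap standard errors (resampling test residual pairs)."""
    rng = np.random.default_rng(seed)
    base = metrics(y_true, y_pred)
    n = base.n
    maes, rmses, r2s = [], [], []
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rep = metrics(y_true[idx], y_pred[idx])
        maes.append(rep.mae)
        rmses.append(rep.rmse)
        r2s.append(rep.r2)
    base.mae_se = float(np.std(maes, ddof=1))
    base.rmse_se = float(np.std(rmses, ddof=1))
    r2s = np.asarray(r2s)
    base.r2_se = float(np.nanstd(r2s, ddof=1))
    return base


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded permutation split into ``folds`` near-equal test index blocks."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, folds)]


def _fit_predict(config, X_tr, y_tr, X_te) -> np.ndarray:
    """Train one configuration and predict; supports ModelConfig, estimator
    factories (callables returning a fresh estimator) and sklearn-style
    estimator prototypes (deep-copied before fitting)."""
    if isinstance(config, ModelConfig):
        model = model_zoo.fit(config, X_tr, y_tr)
        return np.asarray(model_zoo.predict(model, X_te).mean)
    if callable(config) and not hasattr(config, "fit"):
        est = config()
    else:
        est = copy.deepcopy(config)
    est.fit(X_tr, y_tr)
    return np.asarray(est.predict(X_te))


@dataclass
class BbcCvResult:
    oof: np.ndarray  # n x m out-of-fold predictions
    labels: list[str]
    pooled_mae: np.ndarray
    winner: int
    winner_label: str
    winner_report: MetricReport
    corrected_mae: float
    corrected_mae_se: float
    selection_bias: float  # corrected estimate minus winner's pooled MAE
    n_boot: int
    folds: int
    seed: int
    excluded: dict[str, str] = field(default_factory=dict)


def bbc_correct(
    oof: np.ndarray, y: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Bootstrap bias correction on a pooled out-of-fold prediction matrix.

    Returns (corrected MAE, Monte-Carlo SE of the corrected MAE).
    """
    oof = np.asarray(oof, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = oof.shape
    rng = np.random.default_rng(seed)
    abs_err = np.abs(oof - y[:, None])  # n x m
    scores = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        oob = ~mask
        if not oob.any():
            continue
        sel = int(np.argmin(abs_err[idx].mean(axis=0)))
        scores.append(abs_err[oob, sel].mean())
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std(ddof=1) / np.sqrt(scores.size))


def bbc_cv(
    configs: Sequence[tuple],
    X_builder: Callable,
    y: np.ndarray,
    folds: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> BbcCvResult:
    """Joint model selection and bias-corrected performance estimation.

    Parameters
    ----------
    configs
        Sequence of ``(model_config, feature_spec)`` pairs.  ``model_config``
        may be a :class:`~snarpred.model_zoo.ModelConfig`, an estimator
        factory, or an sklearn-style estimator prototype.  ``feature_spec``
        is passed to ``X_builder`` to obtain that configuration's matrix.
    X_builder
        Callable mapping a feature spec to an (n, d) matrix.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not configs:
        raise ValueError("need at least one configuration")
    fold_idx = kfold_indices(n, folds, seed)

    if labels is None:
        labels = []
        for i, (cfg, spec) in enumerate(configs):
            name = cfg.label() if isinstance(cfg, ModelConfig) else type(cfg).__name__
            sname = getattr(spec, "name", "")
            labels.append(f"{name}/{sname}" if sname else f"{name}#{i}")
    labels = list(labels)

    oof_cols, kept_labels, excluded = [], [], {}
    for (cfg, spec), label in zip(configs, labels):
        try:
            X = np.asarray(X_builder(spec), dtype=float)
            col = np.empty(n)
            for test_idx in fold_idx:
                train_mask = np.ones(n, dtype=bool)
                train_mask[test_idx] = False
                col[test_idx] = _fit_predict(cfg, X[train_mask], y[train_mask], X[test_idx])
            oof_cols.append(col)
            kept_labels.append(label)
        except Exception as exc:  # noqa: BLE001 - excluded, never silently scored
            warnings.warn(f"configuration {label!r} excluded: {exc}", stacklevel=2)
            excluded[label] = str(exc)
    if not oof_cols:
        raise RuntimeError("every configuration failed; nothing to select")

    oof = np.column_stack(oof_cols)
    pooled_mae = np.abs(oof - y[:, None]).mean(axis=0)
    winner = int(np.argmin(pooled_mae))
    corrected, corrected_se = bbc_correct(oof, y, n_boot=n_boot, seed=seed)
    winner_report = metrics(y, oof[:, winner])
    return BbcCvResult(
        oof=oof,
        labels=kept_labels,
        pooled_mae=pooled_mae,
        winner=winner,
        winner_label=kept_labels[winner],
        winner_report=winner_report,
        corrected_mae=corrected,
        corrected_mae_se=corrected_se,
        selection_bias=corrected - float(pooled_mae[winner]),
        n_boot=n_boot,
        folds=folds,
        seed=seed,
        excluded=excluded,
    )


@dataclass
class LearningCurve:
    sizes: list[int]
    mean_mae: list[float]
    se_mae: list[float]
    raw: np.ndarray  # len(sizes) x repeats
    seed: int


def learning_curve(
    config,
    X: np.ndarray,
    y: np.ndarray,
    sizes: Sequence[int],
    repeats: int = 5,
    seed: int = 0,
    eval_fraction: float = 0.2,
) -> LearningCurve:
    """Held-out MAE versus training-set size.

    A single seeded evaluation set (``eval_fraction`` of the rows) is held
    out; for each size, training subsets are drawn repeatedly at random from
    the remaining pool and the evaluation MAE is averaged across repeats.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    sizes = [int(s) for s in sizes]
    if sorted(sizes) != sizes or len(set(sizes)) != len(sizes):
        raise ValueError("sizes must be strictly increasing")
    rng = np.random.default_rng(seed)
    n = y.size
    order = rng.permutation(n)
    n_eval = max(1, int(round(eval_fraction * n)))
    eval_idx, pool = order[:n_eval], order[n_eval:]
    if max(sizes) > pool.size:
        raise ValueError(f"max size {max(sizes)} exceeds training pool {pool.size}")
    raw = np.empty((len(sizes), repeats))
    for i, size in enumerate(sizes):
        for j in range(repeats):
            sub = rng.choice(pool, size=size, replace=False)
            pred = _fit_predict(config, X[sub], y[sub], X[eval_idx])
            raw[i, j] = float(np.mean(np.abs(pred - y[eval_idx])))
    se = raw.std(axis=1, ddof=1) / np.sqrt(repeats) if repeats >= 2 else np.full(len(sizes), np.nan)
    return LearningCurve(
        sizes=sizes,
        mean_mae=raw.mean(axis=1).tolist(),
        se_mae=se.tolist(),
        raw=raw,
        seed=seed,
    )


def leave_one_group_out(
    config,
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence,
) -> tuple[MetricReport, np.ndarray]:
    """Predict each group from a model trained on all other groups.

    Returns pooled metrics over all held-out predictions plus the prediction
    vector in original row order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    unique = np.unique(groups)
    if unique.size < 2:
        raise ValueError("need at least 2 groups")
    preds = np.empty_like(y)
    for g in unique:
        test = groups == g
        preds[test] = _fit_predict(config, X[~test], y[~test], X[test])
    return metrics(y, preds), preds
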