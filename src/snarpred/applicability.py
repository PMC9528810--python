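"""Applicability-domain assessment.

Combines a PLS-based distance-to-model metric (DModX), ordering of
predictions by uncertainty (integral accuracy averaging curves), empirical
prediction-interval coverage, and hard categorical gates on reaction class
and reactive-atom types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .reaction_data import DatasetSummary, ReactionRecord

#: Residuals larger than this (kcal/mol) are listed as outliers in AD reports.
OUTLIER_RESIDUAL_KCAL = 2.0


@dataclass
class PlsDmodx:
    """Fitted 2-component PLS X-space model with training residual scale."""

    mean_: np.ndarray
    scale_: np.ndarray
    pls_: PLSRegression
    s0_: float
    n_components: int
    n_train: int

    def _residuals(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        T = Xc @ self.pls_.x_rotations_
        return Xc - T @ self.pls_.x_loadings_.T

    def dmodx(self, X: np.ndarray) -> np.ndarray:
        """Normalized residual distance per row of ``X``."""
        E = self._residuals(X)
        d = E.shape[1]
        s_row = np.sqrt((E**2).sum(axis=1) / (d - self.n_components))
        return s_row / self.s0_


def fit_pls_dmodx(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_components: int = 2,
) -> PlsDmodx:
    """Fit the PLS model used for DModX on training data.

    X is standardized with training statistics; the pooled training residual
    standard deviation s0 uses the classical degrees-of-freedom correction
    (n - a - 1 rows, d - a columns for a components).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n, d = X_train.shape
    if not n_components < min(n, d):
        raise ValueError(f"n_components={n_components} too large for shape {X_train.shape}")
    if np.linalg.matrix_rank(X_train - X_train.mean(axis=0)) < n_components:
        raise ValueError("X rank below the requested number of components")
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    Xc = (X_train - mean) / scale
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xc, y_train)
    E = Xc - (Xc @ pls.x_rotations_) @ pls.x_loadings_.T
    a = n_components
    s0 = np.sqrt((E**2).sum() / ((n - a - 1) * (d - a)))
    return PlsDmodx(
        mean_=mean, scale_=scale, pls_=pls, s0_=float(s0),
        n_components=n_components, n_train=n,
    )


def pls_dmodx(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_query: np.ndarray,
    n_components: int = 2,
) -> np.ndarray:
    """DModX of each query row relative to a PLS model fit on training data."""
    return fit_pls_dmodx(X_train, y_train, n_components).dmodx(X_query)


@dataclass
class AccuracyCurve:
    fractions: np.ndarray  # strictly increasing to 1
    prefix_mae: np.ndarray
    order: np.ndarray  # row order, most certain first


def accuracy_curve(uncertainties: np.ndarray, abs_errors: np.ndarray) -> AccuracyCurve:
    """Prefix MAE with rows ordered from most to least certain.

    Ties in the uncertainty measure are broken by original row order (stable
    sort).  The final point equals the overall MAE exactly.
    """
    u = np.asarray(uncertainties, dtype=float)
    e = np.asarray(abs_errors, dtype=float)
    if u.shape != e.shape or u.ndim != 1 or u.size < 1:
        raise ValueError("need equal-length 1-D vectors with n >= 1")
    order = np.argsort(u, kind="stable")
    sorted_err = e[order]
    n = u.size
    prefix = np.cumsum(sorted_err) / np.arange(1, n + 1)
    # contract: the final point equals the overall MAE exactly (cumsum and
    # pairwise-summed mean can differ in the last ulp)
    prefix[-1] = e.mean()
    return AccuracyCurve(
        fractions=np.arange(1, n + 1) / n,
        prefix_mae=prefix,
        order=order,
    )


def interval_coverage(
    lower: np.ndarray, upper: np.ndarray, y_true: np.ndarray
) -> float:
    """Fraction of targets inside their closed intervals."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if (lower > upper).any():
        bad = np.flatnonzero(lower > upper)
        raise ValueError(f"lower > upper at rows {bad.tolist()[:5]}")
    return float(np.mean((y_true >= lower) & (y_true <= upper)))


def domain_gate(
    record: ReactionRecord,
    training_summary: DatasetSummary,
    reaction_class: str = "SNAr",
    expected_class: str = "SNAr",
) -> tuple[bool, list[str]]:
    """Hard in/out-of-domain decision with enumerated reasons.

    A record is out of domain if its reaction class is not the expected one
    or its (nucleophilic atom, leaving atom) combination never occurs in the
    training set.
    """
    reasons = []
    if reaction_class != expected_class:
        reasons.append(f"reaction class {reaction_class!r} is not {expected_class!r}")
    if not record.nucleophile_class or not record.leaving_class:
        raise ValueError(f"record {record.rxn_id}: missing class annotation")
    combo = (record.nucleophile_class, record.leaving_class)
    if combo not in training_summary.combination_counts:
        if record.nucleophile_class not in training_summary.nucleophile_counts:
            reasons.append(
                f"unseen nucleophilic atom type {record.nucleophile_class!r}"
            )
        if record.leaving_class not in training_summary.leaving_counts:
            reasons.append(f"unseen leaving atom type {record.leaving_class!r}")
        if (
            record.nucleophile_class in training_summary.nucleophile_counts
            and record.leaving_class in training_summary.leaving_counts
        ):
            reasons.append(f"unseen nucleophile/leaving combination {combo!r}")
    return (len(reasons) == 0), reasons


def ad_report(
    rxn_ids,
    dmodx_values: np.ndarray,
    gpr_std: np.ndarray,
    y_true: np.ndarray,
    y_pred: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    in_domain: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-row AD table: DModX, GPR std, coverage flag, absolute error, outlier flag."""
    abs_err = np.abs(np.asarray(y_pred) - np.asarray(y_true))
    covered = (np.asarray(y_true) >= np.asarray(lower)) & (
        np.asarray(y_true) <= np.asarray(upper)
    )
    frame = pd.DataFrame(
        {
            "rxn_id": list(rxn_ids),
            "dmodx": np.asarray(dmodx_values, dtype=float),
            "gpr_std": np.asarray(gpr_std, dtype=float),
            "covered": covered,
            "abs_error": abs_err,
            "outlier": abs_err > OUTLIER_RESIDUAL_KCAL,
        }
    )
    if in_domain is not None:
        frame["in_domain"] = np.asarray(in_domain, dtype=bool)
    return frame
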