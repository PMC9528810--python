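"""Regression model families under one train/predict contract.

Families: linear regression (LR), ARD linear regression optionally with
second-order polynomial features (ARD+PF2), random forest (RF), support
vector regression (SVR), Gaussian-process regression with a Matern-3/2
kernel (GPR), a mean-of-training baseline, and the DFT baselines (raw and
linearly corrected).  GPR returns predictive uncertainty; the other families
return ``std=None``.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import stats
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.linear_model import ARDRegression, LinearRegression
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVR

ModelFamily = Literal["LR", "ARD", "RF", "SVR", "GPR", "mean"]

#: Numerical jitter added to the GPR kernel diagonal for positive definiteness.
GPR_JITTER = 1e-10


def matern32(r: np.ndarray | float, sigma_f2: float = 1.0, ell: float = 1.0):
    """Matern-3/2 covariance k(r) = sigma_f^2 (1 + sqrt(3) r / ell) exp(-sqrt(3) r / ell)."""
    r = np.abs(np.asarray(r, dtype=float))
    s = np.sqrt(3.0) * r / ell
    return sigma_f2 * (1.0 + s) * np.exp(-s)


@dataclass
class ModelConfig:
    family: ModelFamily = "GPR"
    pf2: bool = False
    standardize: bool = True
    seed: int = 0
    # GPR options
    n_restarts: int = 5
    ard_lengthscales: bool = False
    fixed_kernel_params: dict | None = None  # {"sigma_f2", "ell", "sigma_n2"}
    normalize_y: bool = True
    # grid-searched families
    svr_grid: dict = field(
        default_factory=lambda: {
            "C": [1.0, 10.0, 100.0],
            "epsilon": [0.05, 0.1, 0.5],
            "gamma": ["scale"],
        }
    )
    svr_cv: int = 3
    rf_n_estimators: int = 200
    rf_max_features: float | str = 0.33  # decorrelates trees; helps with
    # many correlated, mostly-linear descriptors

    def label(self) -> str:
        return f"{self.family}{'+PF2' if self.pf2 else ''}"


@dataclass
class PredictionWithUncertainty:
    mean: np.ndarray
    std: np.ndarray | None

    def interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        return prediction_interval(self, level)


def _gpr_kernel(config: ModelConfig, n_features: int):
    if config.fixed_kernel_params is not None:
        p = config.fixed_kernel_params
        return (
            ConstantKernel(p["sigma_f2"], constant_value_bounds="fixed")
            * Matern(length_scale=p["ell"], nu=1.5, length_scale_bounds="fixed")
            + WhiteKernel(p["sigma_n2"], noise_level_bounds="fixed")
        )
    ell0 = np.ones(n_features) if config.ard_lengthscales else 1.0
    return (
        ConstantKernel(1.0, (1e-3, 1e4))
        * Matern(length_scale=ell0, nu=1.5, length_scale_bounds=(1e-2, 1e3))
        + WhiteKernel(1e-2, (1e-8, 1e2))
    )


def build_estimator(config: ModelConfig, n_features: int):
    steps = []
    if config.pf2:
        steps.append(("pf2", PolynomialFeatures(degree=2, include_bias=False)))
    if config.standardize and config.family != "RF":
        steps.append(("scale", StandardScaler()))

    if config.family == "LR":
        est = LinearRegression()
    elif config.family == "ARD":
        est = ARDRegression()
    elif config.family == "RF":
        est = RandomForestRegressor(
            n_estimators=config.rf_n_estimators,
            max_features=config.rf_max_features,
            random_state=config.seed,
            n_jobs=1,
        )
    elif config.family == "SVR":
        est = GridSearchCV(
            SVR(kernel="rbf"),
            param_grid=config.svr_grid,
            cv=config.svr_cv,
            scoring="neg_mean_absolute_error",
            n_jobs=1,
        )
    elif config.family == "GPR":
        fixed = config.fixed_kernel_params is not None
        est = GaussianProcessRegressor(
            kernel=_gpr_kernel(config, n_features),
            alpha=GPR_JITTER,
            optimizer=None if fixed else "fmin_l_bfgs_b",
            n_restarts_optimizer=0 if fixed else config.n_restarts,
            normalize_y=False if fixed else config.normalize_y,
            random_state=config.seed,
        )
    elif config.family == "mean":
        est = DummyRegressor(strategy="mean")
    else:
        raise ValueError(f"unknown model family {config.family!r}")
    steps.append(("model", est))
    return Pipeline(steps)


@dataclass
class TrainedModel:
    config: ModelConfig
    pipeline: Pipeline
    columns: list[str] | None = None

    @property
    def is_bayesian(self) -> bool:
        return self.config.family == "GPR"

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def fit(
    config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str] | None = None,
) -> TrainedModel:
    """Train a model; deterministic for fixed config (including seed)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite entries in X or y")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    pipeline = build_estimator(config, X.shape[1])
    pipeline.fit(X, y)
    return TrainedModel(config=config, pipeline=pipeline, columns=columns)


def predict(
    model: TrainedModel,
    X: np.ndarray,
    columns: list[str] | None = None,
) -> PredictionWithUncertainty:
    """Predict; GPR carries the predictive std (noise variance included)."""
    if model.columns is not None and columns is not None:
        missing = [c for c in model.columns if c not in columns]
        extra = [c for c in columns if c not in model.columns]
        if missing or extra:
            raise ValueError(
                f"feature manifest mismatch; missing={missing}, extra={extra}"
            )
    X = np.asarray(X, dtype=float)
    if model.is_bayesian:
        head = model.pipeline[:-1]
        Xt = head.transform(X) if len(head) else X
        mean, std = model.pipeline[-1].predict(Xt, return_std=True)
        return PredictionWithUncertainty(mean=mean, std=std)
    return PredictionWithUncertainty(mean=model.pipeline.predict(X), std=None)


def prediction_interval(
    pred: PredictionWithUncertainty, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Gaussian interval mean +/- z_{(1+level)/2} * std."""
    if pred.std is None:
        raise ValueError(
            "model family provides no predictive std; use a Bayesian family (GPR)"
        )
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * np.asarray(pred.std, dtype=float)
    mean = np.asarray(pred.mean, dtype=float)
    return mean - half, mean + half


@dataclass
class DftBaseline:
    """Predict the experimental barrier directly from the DFT barrier.

    ``raw`` is the identity map; ``linear_corrected`` is an ordinary
    least-squares recalibration dG_exp ~ a + b * dG_dft.
    """

    mode: Literal["raw", "linear_corrected"] = "raw"
    intercept: float = 0.0
    slope: float = 1.0

    def predict(self, dG_dft: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(dG_dft, dtype=float)


def fit_dft_baseline(
    dG_dft: np.ndarray,
    dG_exp: np.ndarray,
    mode: Literal["raw", "linear_corrected"] = "raw",
) -> DftBaseline:
    dG_dft = np.asarray(dG_dft, dtype=float)
    dG_exp = np.asarray(dG_exp, dtype=float)
    if not (np.isfinite(dG_dft).all() and np.isfinite(dG_exp).all()):
        raise ValueError("non-finite barrier values")
    if mode == "raw":
        return DftBaseline(mode="raw")
    if dG_dft.size < 2:
        raise ValueError("linear correction needs n >= 2")
    if np.ptp(dG_dft) == 0:
        raise ValueError("constant dG_dft: linear correction undefined")
    slope, intercept = np.polyfit(dG_dft, dG_exp, 1)
    return DftBaseline(mode="linear_corrected", intercept=float(intercept), slope=float(slope))


def gpr_hyperparameters(model: TrainedModel) -> dict:
    """Fitted (sigma_f2, ell, sigma_n2) of a trained GPR."""
    if not model.is_bayesian:
        raise ValueError("not a GPR model")
    kernel = model.pipeline[-1].kernel_
    prod, white = kernel.k1, kernel.k2
    return {
        "sigma_f2": float(prod.k1.constant_value),
        "ell": np.atleast_1d(prod.k2.length_scale).astype(float),
        "sigma_n2": float(white.noise_level),
    }
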