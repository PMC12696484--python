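"""Regression model pool, nested cross-validated tuning, and metrics.

Six algorithms are compared: Random Forest, k-nearest neighbours, linear
stochastic-gradient-descent regression, a one-hidden-layer MLP, LightGBM
and XGBoost.  Hyperparameters are drawn at random from per-algorithm grids
and scored by 5-fold cross-validated mean absolute error on the training
set (folds shared across algorithms under one seed); the winner is the
algorithm/draw with the lowest MAE_cv.  z-scaling is refit inside every
fold for the scale-sensitive algorithms (kNN and linear SGD) only — the
MLP is deliberately left unscaled to match the documented normalisation
requirements of the pool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import SGDRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor

from .dataset import Scaler
from .errors import ValidationError

log = logging.getLogger(__name__)

try:
    from lightgbm import LGBMRegressor
except ImportError:  # pragma: no cover
    LGBMRegressor = None
try:
    from xgboost import XGBRegressor
except ImportError:  # pragma: no cover
    XGBRegressor = None


@dataclass
class ModelSpec:
    """One algorithm: a sampler over its grid and an estimator factory."""

    algorithm_id: str
    sample_params: callable  # rng -> params dict
    build: callable  # (params, seed) -> unfitted estimator
    needs_scaling: bool = False


def default_model_specs(algorithms: list[str] | None = None) -> list[ModelSpec]:
    """The six-algorithm pool with its default hyperparameter grids."""
    specs = [
        ModelSpec(
            "rf",
            lambda rng: {
                "n_estimators": int(rng.integers(50, 501)),
                "max_depth": int(rng.integers(3, 21)),
                "min_impurity_decrease": float(rng.uniform(0.0, 0.01)),
            },
            lambda p, seed: RandomForestRegressor(random_state=seed, **p),
        ),
        ModelSpec(
            "knn",
            lambda rng: {
                "n_neighbors": int(rng.integers(2, 16)),
                "weights": str(rng.choice(["uniform", "distance"])),
            },
            lambda p, seed: KNeighborsRegressor(**p),
            needs_scaling=True,
        ),
        ModelSpec(
            "sgd_linear",
            lambda rng: {
                "eta0": float(10 ** rng.uniform(-4, -1)),
                "max_iter": int(rng.integers(200, 2001)),
            },
            lambda p, seed: SGDRegressor(random_state=seed, learning_rate="invscaling", **p),
            needs_scaling=True,
        ),
        ModelSpec(
            "mlp",
            lambda rng: {
                "activation": str(rng.choice(["relu", "tanh"])),
                "learning_rate_init": float(10 ** rng.uniform(-4, -2)),
            },
            lambda p, seed: MLPRegressor(
                hidden_layer_sizes=(64,), max_iter=500, random_state=seed, **p
            ),
        ),
    ]
    if LGBMRegressor is not None:
        specs.append(
            ModelSpec(
                "lightgbm",
                lambda rng: {
                    "n_estimators": int(rng.integers(50, 501)),
                    "learning_rate": float(rng.uniform(0.01, 0.3)),
                },
                lambda p, seed: LGBMRegressor(
                    random_state=seed, verbose=-1, min_child_samples=5, **p
                ),
            )
        )
    else:  # pragma: no cover
        log.warning("lightgbm unavailable; algorithm skipped")
    if XGBRegressor is not None:
        specs.append(
            ModelSpec(
                "xgboost",
                lambda rng: {
                    "learning_rate": float(rng.uniform(0.01, 0.3)),
                    "max_depth": int(rng.integers(2, 11)),
                },
                lambda p, seed: XGBRegressor(
                    n_estimators=200, random_state=seed, verbosity=0, **p
                ),
            )
        )
    else:  # pragma: no cover
        log.warning("xgboost unavailable; algorithm skipped")
    if algorithms is not None:
        specs = [s for s in specs if s.algorithm_id in algorithms]
    return specs


@dataclass
class CVResult:
    """Per-algorithm best draw and its cross-validated MAE."""

    mae_cv: dict  # algorithm_id -> best mean MAE over the 5 validation folds
    best_params: dict  # algorithm_id -> params dict
    winner: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "mae_cv": {k: float(v) for k, v in self.mae_cv.items()},
            "best_params": self.best_params,
            "winner": self.winner,
            "seed": self.seed,
        }


@dataclass
class TunedModel:
    """A fitted winner: estimator, optional scaler, and its feature list."""

    algorithm_id: str
    params: dict
    estimator: object
    scaler: Scaler | None
    features: list[str]
    target: str = "viability"

    def _matrix(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.features]
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X.to_numpy(dtype=float)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._matrix(df)), dtype=float)


def _fit_one(spec: ModelSpec, params: dict, X_train, y_train, seed: int):
    """Fit one estimator (with an inner scaler when required); returns
    (estimator, scaler)."""
    scaler = None
    if spec.needs_scaling:
        scaler = Scaler().fit(X_train)
        X_train = scaler.transform(X_train)
    est = spec.build(params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        est.fit(X_train.to_numpy(dtype=float), np.asarray(y_train, dtype=float))
    return est, scaler


def nested_cv(
    train: pd.DataFrame,
    features: list[str],
    target: str,
    specs: list[ModelSpec] | None = None,
    k: int = 5,
    n_draws: int = 25,
    seed: int = 0,
) -> CVResult:
    """Randomised hyperparameter search inside shared k-fold CV.

    Every algorithm sees the same fold partition; for each of ``n_draws``
    sampled parameter combinations the mean validation-fold MAE is
    computed, and the best draw per algorithm is retained.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    specs = default_model_specs() if specs is None else specs
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(train))
    X, y = train[features], train[target]

    mae_cv, best_params = {}, {}
    for s_idx, spec in enumerate(specs):
        rng = np.random.default_rng([seed, s_idx])
        best = (np.inf, None)
        for _ in range(n_draws):
            params = spec.sample_params(rng)
            fold_mae = []
            for tr_idx, va_idx in folds:
                est, scaler = _fit_one(spec, params, X.iloc[tr_idx], y.iloc[tr_idx], seed)
                X_va = X.iloc[va_idx]
                if scaler is not None:
                    X_va = scaler.transform(X_va)
                pred = est.predict(X_va.to_numpy(dtype=float))
                fold_mae.append(np.abs(pred - y.iloc[va_idx].to_numpy()).mean())
            score = float(np.mean(fold_mae))
            if score < best[0]:
                best = (score, params)
        mae_cv[spec.algorithm_id] = best[0]
        best_params[spec.algorithm_id] = best[1]
        log.info("nested CV %s: MAE_cv=%.4f params=%s", spec.algorithm_id, best[0], best[1])

    winner = min(mae_cv, key=mae_cv.get)
    return CVResult(mae_cv=mae_cv, best_params=best_params, winner=winner, seed=seed)


def fit_final(
    train: pd.DataFrame,
    features: list[str],
    target: str,
    spec: ModelSpec,
    params: dict,
    seed: int = 0,
) -> TunedModel:
    """Refit the winning draw on the full training set."""
    est, scaler = _fit_one(spec, params, train[features], train[target], seed)
    return TunedModel(
        algorithm_id=spec.algorithm_id,
        params=dict(params),
        estimator=est,
        scaler=scaler,
        features=list(features),
        target=target,
    )


def regression_metrics(y, y_pred, p: int | None = None) -> dict:
    """R², adjusted R², MAE, MSE and RMSE (RMSE = sqrt(MSE) exactly).

    ``p`` is the model's feature count for the adjusted R²; undefined
    quantities (constant y, or n - p - 1 <= 0) come back as None.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y) != len(y_pred) or len(y) < 2:
        raise ValidationError("y and y_pred must share a length of at least 2")
    n = len(y)
    resid = y - y_pred
    mae = float(np.abs(resid).mean())
    mse = float((resid**2).mean())
    rmse = float(np.sqrt(mse))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = adj = None
    else:
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        adj = None
        if p is not None and n - p - 1 > 0:
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return {"r2": r2, "adjusted_r2": adj, "mae": mae, "mse": mse, "rmse": rmse, "n": n}
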