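"""Post-hoc explanation of a tuned viability model.

Global and local Shapley summaries (positive attributions push predicted
viability up, i.e. toward non-cytotoxicity), permutation importance,
feature-addition performance curves, partial dependence with individual
conditional expectation curves, and per-sample waterfall payloads for
plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .modelling import ModelSpec, TunedModel, fit_final, regression_metrics
from .shapley import shap_values


@dataclass
class Explanation:
    """Global ranking plus the local attribution matrix it was built from."""

    features: list[str]
    local: np.ndarray       # (n_rows, n_features) signed attributions
    base_value: float
    global_table: pd.DataFrame  # feature, mean_abs_shap (descending)
    row_index: list = field(default_factory=list)


def shap_summary(model: TunedModel, data: pd.DataFrame,
                 background: pd.DataFrame | None = None, seed: int = 0) -> Explanation:
    """Shapley attributions of every row plus the mean-|SHAP| ranking."""
    if len(data) == 0:
        raise ValidationError("cannot explain an empty table")
    X = model._matrix(data)
    bg = None if background is None else model._matrix(background)
    phi, base = shap_values(model.estimator, X, background=bg, seed=seed)
    mean_abs = np.abs(phi).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    table = pd.DataFrame(
        {"feature": [model.features[i] for i in order], "mean_abs_shap": mean_abs[order]}
    )
    return Explanation(
        features=list(model.features),
        local=phi,
        base_value=base,
        global_table=table,
        row_index=list(data.index),
    )


def permutation_importance(
    model: TunedModel,
    data: pd.DataFrame,
    target: str = "viability",
    metric: str = "mae",
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean ± sd degradation of the metric when one column is shuffled.

    Degradation is (shuffled metric - baseline) for error metrics and
    (baseline - shuffled) for R², so bigger is always more important.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    y = data[target].to_numpy(dtype=float)

    def score(df):
        m = regression_metrics(y, model.predict(df), p=len(model.features))
        return m[metric]

    baseline = score(data)
    rows = []
    for feature in model.features:
        drops = []
        for _ in range(n_repeats):
            shuffled = data.copy()
            shuffled[feature] = rng.permutation(shuffled[feature].to_numpy())
            s = score(shuffled)
            drops.append((s - baseline) if metric in ("mae", "mse", "rmse") else (baseline - s))
        rows.append((feature, float(np.mean(drops)), float(np.std(drops))))
    out = pd.DataFrame(rows, columns=["feature", "importance_mean", "importance_sd"])
    return out.sort_values("importance_mean", ascending=False, ignore_index=True)


def feature_addition_curve(
    train: pd.DataFrame,
    test: pd.DataFrame,
    ranked_features: list[str],
    target: str,
    spec: ModelSpec,
    params: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Test R²/RMSE of models refit on the top-k feature prefixes, k=1..len."""
    rows = []
    for k in range(1, len(ranked_features) + 1):
        feats = ranked_features[:k]
        model = fit_final(train, feats, target, spec, params, seed=seed)
        m = regression_metrics(test[target], model.predict(test), p=k)
        rows.append({"k": k, "last_added": feats[-1], "r2": m["r2"], "rmse": m["rmse"]})
    return pd.DataFrame(rows)


def _grid_for(values: np.ndarray, grid):
    if grid is None:
        # deciles of the observed distribution, deduplicated
        return np.unique(np.quantile(values, np.linspace(0, 1, 10)))
    return np.asarray(grid, dtype=float)


def pdp_ice(
    model: TunedModel,
    data: pd.DataFrame,
    features: str | tuple[str, str],
    grid=None,
    centred: bool = False,
) -> dict:
    """Partial dependence and ICE curves by feature substitution.

    For a single feature: PDP(g) = mean over rows of the prediction with
    the feature forced to g; ICE keeps the per-row curves (the PDP is
    their mean at every grid point).  ``centred`` subtracts each curve's
    first value.  A feature pair yields a 2-D PDP surface on a grid
    (default 10x10 deciles).
    """
    if isinstance(features, (tuple, list)) and len(features) == 2:
        f1, f2 = features
        for f in (f1, f2):
            if f not in model.features:
                raise ValidationError(f"feature {f!r} is not in the model")
        g1 = _grid_for(data[f1].to_numpy(dtype=float), grid[0] if grid else None)
        g2 = _grid_for(data[f2].to_numpy(dtype=float), grid[1] if grid else None)
        surface = np.empty((len(g1), len(g2)))
        work = data.copy()
        for i, a in enumerate(g1):
            for j, b in enumerate(g2):
                work[f1] = a
                work[f2] = b
                surface[i, j] = model.predict(work).mean()
        return {"features": (f1, f2), "grid": (g1, g2), "pdp": surface}

    feature = features
    if feature not in model.features:
        raise ValidationError(f"feature {feature!r} is not in the model")
    g = _grid_for(data[feature].to_numpy(dtype=float), grid)
    ice = np.empty((len(data), len(g)))
    work = data.copy()
    for j, value in enumerate(g):
        work[feature] = value
        ice[:, j] = model.predict(work)
    if centred:
        ice = ice - ice[:, [0]]
    return {"feature": feature, "grid": g, "ice": ice, "pdp": ice.mean(axis=0)}


def waterfall_export(model: TunedModel, row: pd.DataFrame,
                     background: pd.DataFrame | None = None, seed: int = 0) -> dict:
    """Per-sample signed contributions sorted by magnitude, plot-ready.

    The payload satisfies base_value + Σ contributions = prediction.
    """
    if len(row) != 1:
        raise ValidationError("waterfall_export explains exactly one row")
    exp = shap_summary(model, row, background=background, seed=seed)
    contrib = exp.local[0]
    order = np.argsort(-np.abs(contrib), kind="stable")
    return {
        "base_value": exp.base_value,
        "prediction": float(exp.base_value + contrib.sum()),
        "contributions": [
            {
                "feature": model.features[i],
                "value": float(row.iloc[0][model.features[i]]),
                "contribution": float(contrib[i]),
            }
            for i in order
        ],
    }
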