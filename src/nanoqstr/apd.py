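"""Distance-based applicability domain with a mixed-type option.

All pairwise distances between training rows are computed; the subset of
distances strictly below their mean is retained, and its mean <d> and
sample standard deviation σ form the threshold ``<d> + Z·σ``.  A query is
reliable iff the distance to its nearest training neighbour does not
exceed the threshold.  Two metrics are supported: Euclidean on the numeric
feature block (categorical attributes excluded) and a weighted Gower
distance over mixed numeric/categorical features, where numeric
differences are range-normalised on the training data and clipped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .errors import ValidationError


def gower_distance(x, y, weights, ranges, categorical_mask) -> float:
    """Weighted Gower dissimilarity between two rows, in [0, 1].

    Numeric contributions are |x-y| / range clipped at 1; categorical
    contributions are 0/1 mismatch.  Zero-range numeric features are
    skipped (with a warning at fit time).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValidationError("weights must be non-negative and not all zero")
    cat = np.asarray(categorical_mask, dtype=bool)
    ranges = np.asarray(ranges, dtype=float)
    d = np.empty(len(x))
    d[cat] = (x[cat] != y[cat]).astype(float)
    num = ~cat
    usable = num & (ranges > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d[usable] = np.minimum(np.abs(x[usable] - y[usable]) / ranges[usable], 1.0)
    skip = num & ~usable
    w = w.copy()
    w[skip] = 0.0
    return float((w * d).sum() / w.sum())


def _gower_matrix(X, Y, weights, ranges, cat_mask) -> np.ndarray:
    """Pairwise weighted Gower distances between row sets (vectorised)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    w = np.asarray(weights, dtype=float).copy()
    cat = np.asarray(cat_mask, dtype=bool)
    usable_num = ~cat & (np.asarray(ranges, dtype=float) > 0)
    w[~cat & ~usable_num] = 0.0
    total_w = w.sum()
    out = np.zeros((len(X), len(Y)))
    for k in np.flatnonzero(w > 0):
        xk = X[:, k][:, None]
        yk = Y[:, k][None, :]
        if cat[k]:
            dk = (xk != yk).astype(float)
        else:
            dk = np.minimum(np.abs(xk - yk) / ranges[k], 1.0)
        out += w[k] * dk
    return out / total_w


@dataclass
class APDModel:
    """Fitted applicability domain: reference rows, metric and threshold."""

    metric: str
    columns: list[str]
    reference: np.ndarray
    mean_retained: float  # <d>
    sd_retained: float    # σ (sample sd of the retained distances)
    Z: float
    threshold: float
    weights: np.ndarray | None = None
    ranges: np.ndarray | None = None
    categorical_mask: np.ndarray | None = None
    scaler_means: pd.Series | None = None
    scaler_sds: pd.Series | None = None

    def _matrix(self, df: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise ValidationError(f"query is missing APD feature columns: {missing}")
        X = df[self.columns].astype(float)
        if self.scaler_means is not None:
            X = (X - self.scaler_means) / self.scaler_sds
        return X.to_numpy()

    def distances_to_training(self, df: pd.DataFrame) -> np.ndarray:
        Q = self._matrix(df)
        if self.metric == "euclidean":
            return cdist(Q, self.reference)
        return _gower_matrix(Q, self.reference, self.weights, self.ranges,
                             self.categorical_mask)

    def in_domain(self, df: pd.DataFrame) -> pd.DataFrame:
        """Nearest-training-neighbour distance and reliability per query row.

        Reliable iff the nearest distance does not *exceed* the threshold
        (inclusive at the boundary).
        """
        nearest = self.distances_to_training(df).min(axis=1)
        return pd.DataFrame(
            {
                "nearest_distance": nearest,
                "threshold": self.threshold,
                "reliable": nearest <= self.threshold + 1e-12,
            },
            index=df.index,
        )

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "columns": list(self.columns),
            "mean_retained": self.mean_retained,
            "sd_retained": self.sd_retained,
            "Z": self.Z,
            "threshold": self.threshold,
            "n_reference": len(self.reference),
        }


def fit_apd(
    train: pd.DataFrame,
    metric: str = "euclidean",
    Z: float = 0.5,
    weights: dict | np.ndarray | None = None,
    categorical_columns: list[str] | None = None,
    scale_numeric: bool = True,
) -> APDModel:
    """Fit the <d> + Zσ applicability-domain threshold on training features.

    Euclidean mode drops the categorical columns and (by default)
    z-scales the numeric block on the training statistics; Gower mode
    keeps every column, range-normalising numeric features.  ``weights``
    (Gower only) may be a column -> weight mapping, e.g. normalised mean
    |SHAP| importances of the final model.
    """
    if len(train) < 3:
        raise ValidationError("APD needs at least 3 training rows")
    categorical_columns = list(categorical_columns or [])

    if metric == "euclidean":
        columns = [c for c in train.columns if c not in categorical_columns]
        X = train[columns].astype(float)
        means = sds = None
        if scale_numeric:
            means = X.mean()
            sds = X.std(ddof=0).replace(0.0, 1.0)
            X = (X - means) / sds
        ref = X.to_numpy()
        dists = pdist(ref)
        extra = {"scaler_means": means, "scaler_sds": sds}
    elif metric == "gower":
        columns = list(train.columns)
        ref = train[columns].astype(float).to_numpy()
        cat = np.array([c in categorical_columns for c in columns])
        ranges = np.where(cat, 1.0, ref.max(axis=0) - ref.min(axis=0))
        zero_rng = ~cat & (ranges <= 0)
        if zero_rng.any():
            warnings.warn(
                f"zero-range numeric features skipped in Gower distance: "
                f"{[c for c, z in zip(columns, zero_rng) if z]}", stacklevel=2,
            )
        if weights is None:
            w = np.ones(len(columns))
        elif isinstance(weights, dict):
            w = np.array([float(weights.get(c, 0.0)) for c in columns])
            if w.sum() == 0:
                w = np.ones(len(columns))
        else:
            w = np.asarray(weights, dtype=float)
        full = _gower_matrix(ref, ref, w, ranges, cat)
        dists = full[np.triu_indices(len(ref), k=1)]
        extra = {"weights": w, "ranges": ranges, "categorical_mask": cat}
    else:
        raise ValidationError(f"unknown APD metric {metric!r}")

    retained = dists[dists < dists.mean()]
    if len(retained) < 2:
        raise ValidationError(
            "all pairwise training distances are (nearly) equal; the "
            "retain-below-mean rule leaves nothing to estimate a threshold "
            "from — add more diverse training rows or use a different metric"
        )
    mean_d = float(retained.mean())
    sd_d = float(retained.std(ddof=1))
    return APDModel(
        metric=metric,
        columns=columns,
        reference=ref,
        mean_retained=mean_d,
        sd_retained=sd_d,
        Z=float(Z),
        threshold=mean_d + float(Z) * sd_d,
        **extra,
    )
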