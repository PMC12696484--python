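"""Feature selection for the descriptor-augmented table.

Zero-variance and pairwise Pearson-correlation filters prune the redundant
(mostly size-collinear) atomistic descriptors; a Random Forest surrogate
(40 trees, depth 10) with Shapley attributions then ranks the survivors,
and the top-k atomistic descriptors are united with the five experimental
exposure features that are known before synthesis (core size, coating
group, shell material, shell thickness, concentration).  Selection runs on
training rows only so no information leaks from the hold-out set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .dataset import EXPERIMENTAL_FIVE
from .errors import ValidationError
from .shapley import shap_values

log = logging.getLogger(__name__)


@dataclass
class FeatureSelection:
    """Audit trail of the reduction: what was dropped, why, and the ranking."""

    dropped_zero_variance: list = field(default_factory=list)
    dropped_correlated: list = field(default_factory=list)  # (kept, dropped, r)
    shap_ranking: list = field(default_factory=list)  # (feature, mean |SHAP|) desc
    final_set: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_zero_variance": list(self.dropped_zero_variance),
            "dropped_correlated": [(a, b, float(r)) for a, b, r in self.dropped_correlated],
            "shap_ranking": [(f, float(s)) for f, s in self.shap_ranking],
            "final_set": list(self.final_set),
        }


def variance_correlation_filter(
    train: pd.DataFrame,
    features: list[str],
    threshold: float = 0.99,
) -> tuple[list[str], list[str], list[tuple]]:
    """Drop constant columns, then greedily drop the later member of any
    feature pair with |Pearson r| > ``threshold`` (registry-order stable).

    Returns (survivors, dropped_zero_variance, dropped_correlated).
    """
    if len(train) < 2:
        raise ValidationError("need at least two training rows to filter")
    values = train[features]
    sds = values.std(ddof=0)
    zero_var = [f for f in features if sds[f] == 0 or not np.isfinite(sds[f])]
    alive = [f for f in features if f not in zero_var]

    corr = values[alive].corr().to_numpy() if alive else np.empty((0, 0))
    dropped_pairs: list[tuple] = []
    keep_mask = np.ones(len(alive), dtype=bool)
    for j in range(len(alive)):
        if not keep_mask[j]:
            continue
        for i in range(j):
            if keep_mask[i] and abs(corr[i, j]) > threshold:
                keep_mask[j] = False
                dropped_pairs.append((alive[i], alive[j], corr[i, j]))
                break
    survivors = [f for f, k in zip(alive, keep_mask) if k]
    return survivors, zero_var, dropped_pairs


def shap_rank_select(
    train: pd.DataFrame,
    target: str,
    atomistic_features: list[str],
    experimental_features: list[str] | None = None,
    k: int = 8,
    seed: int = 0,
    corr_threshold: float = 0.99,
    background_size: int = 64,
) -> FeatureSelection:
    """Filter, rank by mean |SHAP| of a Random Forest surrogate, keep top-k.

    The surrogate (40 estimators, max depth 10) is trained on the filtered
    atomistic pool plus the experimental features; ranking considers the
    atomistic descriptors only, and the final set unites the top-k with the
    fixed experimental five.  Ties break by registry order.
    """
    experimental = list(EXPERIMENTAL_FIVE if experimental_features is None else experimental_features)
    if len(train) < 20:
        raise ValidationError("need at least 20 training rows for SHAP ranking")

    survivors, zero_var, dropped_pairs = variance_correlation_filter(
        train, atomistic_features, threshold=corr_threshold
    )
    if k > len(survivors):
        log.warning("k=%d exceeds the %d surviving atomistic features; keeping all",
                    k, len(survivors))
        k = len(survivors)

    pool = experimental + survivors
    X = train[pool].to_numpy(dtype=float)
    y = train[target].to_numpy(dtype=float)
    surrogate = RandomForestRegressor(
        n_estimators=40, max_depth=10, random_state=seed
    ).fit(X, y)

    rng = np.random.default_rng(seed)
    bg = X if len(X) <= background_size else X[rng.choice(len(X), background_size, replace=False)]
    phi, _ = shap_values(surrogate, X, background=bg, seed=seed)
    importance = np.abs(phi).mean(axis=0)

    atom_scores = {f: importance[pool.index(f)] for f in survivors}
    # stable sort: descending score, registry order breaks ties
    ranking = sorted(survivors, key=lambda f: (-atom_scores[f], survivors.index(f)))
    top = ranking[:k]

    return FeatureSelection(
        dropped_zero_variance=zero_var,
        dropped_correlated=dropped_pairs,
        shap_ranking=[(f, atom_scores[f]) for f in ranking],
        final_set=experimental + top,
    )
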