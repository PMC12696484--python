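"""Model acceptability assessment: LOO Q², Golbraikh–Tropsha criteria,
response scrambling and bootstrap confidence intervals.

A regression QSTR is accepted for external prediction when, on the blind
set, r² > 0.6, the leave-one-out Q² of the training set exceeds 0.5, at
least one normalised gap between r² and a through-origin determination
coefficient is below 0.1, and at least one of the through-origin slopes
k, k' lies in (0.85, 1.15).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from .errors import ValidationError
from .modelling import ModelSpec, _fit_one, fit_final, regression_metrics


def loo_q2(train: pd.DataFrame, features: list[str], target: str,
           spec: ModelSpec, params: dict, seed: int = 0) -> float:
    """Leave-one-out cross-validated Q² = 1 - PRESS / SS_tot.

    Each held-out prediction comes from a model refit on the other n-1
    rows with the *same* hyperparameters (scaling refit inside).
    """
    n = len(train)
    if n < 3:
        raise ValidationError("LOO Q² needs at least 3 rows")
    y = train[target].to_numpy(dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValidationError("constant response: Q² undefined")
    press = 0.0
    for i in range(n):
        rest = train.drop(index=train.index[i])
        est, scaler = _fit_one(spec, params, rest[features], rest[target], seed)
        row = train[features].iloc[[i]]
        if scaler is not None:
            row = scaler.transform(row)
        pred = float(est.predict(row.to_numpy(dtype=float))[0])
        press += (y[i] - pred) ** 2
    return 1.0 - press / ss_tot


@dataclass
class GTReport:
    """Golbraikh–Tropsha quantities with individual pass flags."""

    r2: float
    q2_loo: float | None
    k: float
    k_prime: float
    r0_sq: float
    r0_prime_sq: float
    ratio: float          # (r² - r0²) / r²
    ratio_prime: float    # (r² - r0'²) / r²
    flags: dict

    @property
    def passed(self) -> bool:
        return all(v for v in self.flags.values() if v is not None)

    def to_dict(self) -> dict:
        out = {
            "r2": self.r2, "q2_loo": self.q2_loo, "k": self.k, "k_prime": self.k_prime,
            "r0_sq": self.r0_sq, "r0_prime_sq": self.r0_prime_sq,
            "ratio": self.ratio, "ratio_prime": self.ratio_prime,
            "passed": self.passed,
        }
        out["flags"] = dict(self.flags)
        return out


def golbraikh_tropsha(y, y_pred, q2_loo: float | None = None) -> GTReport:
    """Through-origin slopes/determination coefficients and pass flags.

    k  = Σ y ŷ / Σ ŷ² ;  k' = Σ y ŷ / Σ y²
    r0²  = 1 - Σ(y - k ŷ)²  / Σ(y - ȳ)²
    r0'² = 1 - Σ(ŷ - k' y)² / Σ(ŷ - ŷ̄)²

    Overall pass: r² > 0.6, Q²loo > 0.5 (when provided), at least one of
    the two (r² - r0²)/r² ratios < 0.1, and at least one slope in
    (0.85, 1.15).
    """
    y = np.asarray(y, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if len(y) < 3:
        raise ValidationError("Golbraikh-Tropsha needs at least 3 points")
    if np.std(y) == 0 or np.std(yp) == 0:
        raise ValidationError("constant observed or predicted values")

    r = np.corrcoef(y, yp)[0, 1]
    r2 = float(r**2)
    k = float((y * yp).sum() / (yp**2).sum())
    kp = float((y * yp).sum() / (y**2).sum())
    ss_y = float(((y - y.mean()) ** 2).sum())
    ss_yp = float(((yp - yp.mean()) ** 2).sum())
    r0 = 1.0 - float(((y - k * yp) ** 2).sum()) / ss_y
    r0p = 1.0 - float(((yp - kp * y) ** 2).sum()) / ss_yp
    ratio = (r2 - r0) / r2 if r2 != 0 else np.inf
    ratio_p = (r2 - r0p) / r2 if r2 != 0 else np.inf

    flags = {
        "r2_gt_0.6": r2 > 0.6,
        "q2_loo_gt_0.5": None if q2_loo is None else q2_loo > 0.5,
        "ratio_lt_0.1": min(ratio, ratio_p) < 0.1,
        "slope_in_window": (0.85 < k < 1.15) or (0.85 < kp < 1.15),
    }
    return GTReport(
        r2=r2, q2_loo=q2_loo, k=k, k_prime=kp, r0_sq=float(r0),
        r0_prime_sq=float(r0p), ratio=float(ratio), ratio_prime=float(ratio_p),
        flags=flags,
    )


def y_scramble(
    train: pd.DataFrame,
    test: pd.DataFrame,
    features: list[str],
    target: str,
    spec: ModelSpec,
    params: dict,
    n_rounds: int = 5,
    seed: int = 0,
) -> dict:
    """Refit on a permuted training response and score the real test set.

    A model that learned genuine structure must beat every scrambled
    round; the verdict is "separated" when the true test R² exceeds all
    scrambled R², else "indistinguishable".
    """
    rng = np.random.default_rng(seed)
    true_model = fit_final(train, features, target, spec, params, seed=seed)
    y_test = test[target].to_numpy(dtype=float)
    true_metrics = regression_metrics(y_test, true_model.predict(test), p=len(features))

    rounds = []
    for _ in range(n_rounds):
        shuffled = train.copy()
        shuffled[target] = rng.permutation(shuffled[target].to_numpy())
        model = fit_final(shuffled, features, target, spec, params, seed=seed)
        rounds.append(regression_metrics(y_test, model.predict(test), p=len(features)))

    if not rounds:
        return {"true": true_metrics, "rounds": [], "verdict": None}
    true_r2 = -np.inf if true_metrics["r2"] is None else true_metrics["r2"]
    scrambled_r2 = [(-np.inf if r["r2"] is None else r["r2"]) for r in rounds]
    verdict = "separated" if all(true_r2 > r for r in scrambled_r2) else "indistinguishable"
    return {"true": true_metrics, "rounds": rounds, "verdict": verdict}


def bootstrap_ci(
    df: pd.DataFrame,
    features: list[str],
    target: str,
    spec: ModelSpec,
    params: dict,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Percentile bootstrap CIs for out-of-bag MAE and R².

    Each of the ``B`` resamples refits the model and scores the rows left
    out of the resample; resamples whose out-of-bag set is empty (or too
    small for R²) are skipped and counted.
    """
    if B < 50:
        raise ValidationError("B must be >= 50 for stable percentile intervals")
    rng = np.random.default_rng(seed)
    n = len(df)
    maes, r2s = [], []
    skipped = 0
    never_oob = np.ones(n, dtype=bool)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) < 2:
            skipped += 1
            continue
        never_oob[oob] = False
        model = fit_final(df.iloc[idx], features, target, spec, params, seed=seed)
        m = regression_metrics(df[target].iloc[oob], model.predict(df.iloc[oob]),
                               p=len(features))
        maes.append(m["mae"])
        if m["r2"] is not None:
            r2s.append(m["r2"])
    alpha = (1 - level) / 2
    point_model = fit_final(df, features, target, spec, params, seed=seed)
    point = regression_metrics(df[target], point_model.predict(df), p=len(features))

    def ci(vals):
        return (
            (float(np.quantile(vals, alpha)), float(np.quantile(vals, 1 - alpha)))
            if vals else (None, None)
        )

    return {
        "mae_ci": ci(maes),
        "r2_ci": ci(r2s),
        "mae_mean": float(np.mean(maes)) if maes else None,
        "r2_mean": float(np.mean(r2s)) if r2s else None,
        "point": point,
        "skipped_resamples": skipped,
        "rows_never_oob": int(never_oob.sum()),
        "B": B,
        "level": level,
    }
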