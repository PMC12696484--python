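"""Curation of the tabular viability dataset.

One row per treatment: a nanoparticle (phase, core diameter, shell,
coating), an exposure (concentration, cell line) and the measured cell
viability at 24 h as a fraction of the untreated control.  This module
encodes the categorical attributes, labels cytotoxicity with the ISO
<70 %-of-control rule, performs the constrained stratified 70:30 split,
z-scales features on training statistics only, and joins the atomistic
descriptor table onto the treatment rows.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

#: Viability fraction below which a treatment counts as cytotoxic (strict).
CYTOTOXIC_THRESHOLD = 0.70

EXPERIMENTAL_FIVE = [
    "core_diameter",
    "coating_group",
    "shell_material",
    "shell_thickness",
    "concentration",
]

CATEGORICAL_COLUMNS = ["shell_material", "coating_group", "cell_line", "organism", "health_status"]

#: Columns accepted on input but dropped from the analysis.
DROPPED_COLUMNS = ["zeta_potential", "hydrodynamic_size"]

COATING_GROUP_ORDINALS = {"bare": 0, "polymer-based": 1, "protein-based": 2, "other": 3}

#: Keyword table mapping free-text surface modifiers to functional groups.
COATING_KEYWORDS = {
    "polymer-based": [
        "peg", "polyethylene glycol", "poly", "pluronic", "pvp", "pva",
        "dextran", "chitosan", "pei",
    ],
    "protein-based": [
        "albumin", "bsa", "protein", "transferrin", "antibody", "casein",
    ],
}


def coating_group(coating) -> str:
    """Free-text surface modifier -> functional group label."""
    if coating is None or (isinstance(coating, float) and np.isnan(coating)):
        return "bare"
    text = str(coating).strip().lower()
    if text in ("", "none", "bare", "uncoated", "nan"):
        return "bare"
    for group, keywords in COATING_KEYWORDS.items():
        if any(k in text for k in keywords):
            return group
    return "other"


def read_viability_csv(path) -> pd.DataFrame:
    """Read a treatment table; viability given in % is converted to fraction."""
    df = pd.read_csv(path)
    if "viability" not in df.columns:
        raise ValidationError("viability column is required")
    if df["viability"].max() > 2.0:  # percent scale
        df["viability"] = df["viability"] / 100.0
    for col in DROPPED_COLUMNS:
        if col in df.columns:
            df = df.drop(columns=col)
            log.info("dropped column %s (not used in the analysis)", col)
    return df


def label_cytotoxicity(viability) -> np.ndarray:
    """Cytotoxic iff viability < 0.70 of control (strict inequality)."""
    v = np.asarray(viability, dtype=float)
    if (v < 0).any():
        raise ValidationError("viability must be non-negative")
    return np.where(v < CYTOTOXIC_THRESHOLD, "cytotoxic", "non-cytotoxic")


# ---------------------------------------------------------------------------
# encoding

@dataclass
class Encoder:
    """Ordinal/binary encoding of the categorical attributes.

    Coating groups use fixed ordinals (bare=0, polymer=1, protein=2,
    other=3); shell material and cell line are ordinal by descending
    training frequency; health status and organism are binary.  The fitted
    mapping is persistable so that predictions reuse the training encoding.
    """

    mappings: dict = field(default_factory=dict)

    def fit(self, df: pd.DataFrame) -> "Encoder":
        self.mappings = {"coating_group": dict(COATING_GROUP_ORDINALS)}
        for col in ("shell_material", "cell_line"):
            if col in df.columns:
                order = df[col].astype(str).value_counts().index.tolist()
                self.mappings[col] = {cat: i for i, cat in enumerate(order)}
        if "health_status" in df.columns:
            self.mappings["health_status"] = {"normal": 0, "cancer": 1}
        if "organism" in df.columns:
            order = sorted(df["organism"].astype(str).unique())
            self.mappings["organism"] = {cat: i for i, cat in enumerate(order[:2])}
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if not self.mappings:
            raise ValidationError("encoder must be fitted before transform")
        out = df.copy()
        if "coating" in out.columns and "coating_group" not in out.columns:
            out["coating_group"] = out["coating"].map(coating_group)
        for col, mapping in self.mappings.items():
            if col not in out.columns:
                continue
            vals = out[col].astype(str)
            unseen = ~vals.isin(mapping)
            if unseen.any():
                # unseen categories fall back to the most frequent training
                # code; flagged so the applicability domain can veto them
                fallback = min(mapping.values())
                log.warning(
                    "column %s: %d unseen categories mapped to fallback code %d",
                    col, int(unseen.sum()), fallback,
                )
                out[col] = vals.map(mapping).fillna(fallback).astype(int)
                out[col + "_unseen"] = unseen.astype(int)
            else:
                out[col] = vals.map(mapping).astype(int)
        if "coating" in out.columns:
            out = out.drop(columns="coating")
        return out

    def to_json(self) -> str:
        return json.dumps(self.mappings, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Encoder":
        return cls(mappings=json.loads(text))


def encode_records(df: pd.DataFrame, encoder: Encoder | None = None) -> tuple[pd.DataFrame, Encoder]:
    """Encode categoricals; fits a fresh encoder on ``df`` when none given."""
    work = df.copy()
    if "coating" in work.columns and "coating_group" not in work.columns:
        work["coating_group"] = work["coating"].map(coating_group)
    if encoder is None:
        encoder = Encoder().fit(work)
    return encoder.transform(df), encoder


# ---------------------------------------------------------------------------
# splitting

@dataclass
class SplitIndex:
    """Row labels of the train/test partition plus the strata used."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int
    strata: pd.Series

    @property
    def test_fraction(self) -> float:
        return len(self.test_ids) / (len(self.train_ids) + len(self.test_ids))


def stratified_split(
    df: pd.DataFrame,
    test_frac: float = 0.30,
    seed: int = 0,
    experiment_col: str = "experiment_id",
) -> SplitIndex:
    """Constrained 70:30 split.

    (1) one uniformly chosen row of every multi-row experiment goes to the
    test set, so every chemistry is represented in the hold-out; (2) the
    remaining test quota is filled by stratified sampling on the binary
    cytotoxicity label.  Single-row experiments stay in training (a warning
    is raised).  Deterministic under ``seed``.
    """
    if not 0 < test_frac < 1:
        raise ValidationError(f"test_frac must be in (0, 1), got {test_frac}")
    rng = np.random.default_rng(seed)
    strata = pd.Series(label_cytotoxicity(df["viability"]), index=df.index, name="stratum")

    test_idx: list = []
    for _, group in df.groupby(experiment_col, sort=True):
        if len(group) < 2:
            warnings.warn(
                f"experiment {group[experiment_col].iloc[0]!r} has a single row; "
                "kept in training", stacklevel=2,
            )
            continue
        test_idx.append(rng.choice(group.index.to_numpy()))

    quota = int(round(test_frac * len(df)))
    remaining = [i for i in df.index if i not in set(test_idx)]
    need = quota - len(test_idx)
    if need > 0:
        props = strata.value_counts(normalize=True)
        in_test = strata.loc[test_idx].value_counts().to_dict()
        pools = {
            label_: list(rng.permutation([i for i in remaining if strata.loc[i] == label_]))
            for label_ in props.index
        }
        # fill one slot at a time toward the label with the largest deficit
        # against its ideal quota share (greedy, deviation-minimising)
        for _ in range(need):
            deficits = {
                label_: quota * props[label_] - in_test.get(label_, 0)
                for label_ in props.index if pools[label_]
            }
            if not deficits:
                break
            label_ = max(sorted(deficits), key=deficits.get)
            test_idx.append(pools[label_].pop())
            in_test[label_] = in_test.get(label_, 0) + 1

    test_set = set(test_idx)
    train_idx = [i for i in df.index if i not in test_set]
    return SplitIndex(
        train_ids=np.array(train_idx),
        test_ids=np.array(sorted(test_set, key=list(df.index).index)),
        seed=seed,
        strata=strata,
    )


# ---------------------------------------------------------------------------
# scaling

@dataclass
class Scaler:
    """Column-wise z-score learned on training rows (population sd).

    Constant columns pass through unscaled (sd forced to 1) with a warning.
    """

    means: pd.Series | None = None
    sds: pd.Series | None = None
    ddof: int = 0

    def fit(self, df: pd.DataFrame) -> "Scaler":
        if len(df) == 0:
            raise ValidationError("cannot fit a scaler on an empty table")
        self.means = df.mean()
        sds = df.std(ddof=self.ddof)
        constant = sds == 0
        if constant.any():
            warnings.warn(
                f"constant columns pass through unscaled: {list(sds.index[constant])}",
                stacklevel=2,
            )
            sds = sds.mask(constant, 1.0)
            self.means = self.means.mask(constant, 0.0)
        self.sds = sds
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.means is None:
            raise ValidationError("scaler must be fitted before transform")
        return (df - self.means[df.columns]) / self.sds[df.columns]

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return df * self.sds[df.columns] + self.means[df.columns]


def fit_apply_scaler(train: pd.DataFrame, *others: pd.DataFrame):
    """Fit on the training block, apply to training plus any other blocks."""
    scaler = Scaler().fit(train)
    return (scaler, scaler.transform(train), *[scaler.transform(o) for o in others])


# ---------------------------------------------------------------------------
# descriptor join

def join_descriptors(
    table: pd.DataFrame,
    descriptors: pd.DataFrame,
    tol: float = 0.1,
) -> pd.DataFrame:
    """Attach D1..D57 columns by nearest-diameter match within ``tol`` nm.

    ``descriptors`` must carry ``phase`` and ``diameter_nm`` plus the
    descriptor columns.  Unmatched or ambiguous (phase, diameter) pairs
    raise with the offending pairs listed.
    """
    if len(descriptors) == 0:
        raise ValidationError("descriptor table is empty")
    desc_cols = [c for c in descriptors.columns if c.startswith("D")]
    rows, problems = [], []
    for phase, diam in table[["phase", "core_diameter"]].itertuples(index=False):
        cand = descriptors[descriptors["phase"] == phase]
        cand = cand[(cand["diameter_nm"] - diam).abs() <= tol + 1e-12]
        if len(cand) == 0:
            problems.append((phase, diam, "missing"))
            rows.append(None)
        elif len(cand) > 1:
            problems.append((phase, diam, "ambiguous"))
            rows.append(None)
        else:
            rows.append(cand.iloc[0][desc_cols])
    if problems:
        raise ValidationError(f"unmatched descriptor particles: {sorted(set(problems))}")
    desc_block = pd.DataFrame(rows, index=table.index)
    return pd.concat([table, desc_block], axis=1)
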