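"""End-to-end orchestration of the nano-QSTR workflow.

Stages: load or simulate the viability table → build proxy nanoparticles
and their descriptor table (atomistic approach only) → curate, label and
split → select features → tune models under nested CV → final fit and
external validation (metrics, Golbraikh–Tropsha, LOO Q², y-scrambling,
bootstrap) → applicability domain (Euclidean and Gower) → explanation →
QMRF-style report.  Each stage records its outputs on a
:class:`PipelineState` that can be persisted and reloaded, which is what
the command-line interface drives.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import apd as apd_mod
from . import crystal, dataset, descriptors, explain, featsel, modelling, synthdata, validation
from .energy import LennardJonesModel, MorseModel
from .errors import ValidationError

log = logging.getLogger(__name__)

EVIDENCE_FEATURES = [
    "core_diameter", "size_sd", "shell_material", "shell_thickness",
    "coating_group", "concentration", "cell_line", "organism", "health_status",
]

#: Encoded-ordinal columns treated as categorical by the applicability domain.
APD_CATEGORICAL = ["shell_material", "coating_group", "cell_line", "organism", "health_status"]


@dataclass
class RunConfig:
    """Every knob of a pipeline run; YAML-loadable."""

    approach: str = "atomistic"            # "atomistic" | "evidence"
    dataset_csv: str | None = None         # None -> simulate the default scenario
    cif_dir: str | None = None             # None -> write toy CIFs under out_dir
    out_dir: str | None = None
    seed: int = 0
    test_frac: float = 0.30
    scale_ang_per_nm: float = 2.0          # proxy-particle scale (Å per nominal nm)
    shell_depth: float = 4.0               # Å
    center_policy: str = "atom"
    energy_model: str = "lj"               # "lj" | "morse"
    algorithms: list | None = None         # None -> full six-algorithm pool
    n_draws: int = 25
    k_top: int = 8
    apd_z: float = 0.5
    bootstrap_B: int = 200
    scramble_rounds: int = 5
    n_permutation_repeats: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineState:
    """Mutable record of a run: inputs, intermediates and results."""

    config: RunConfig
    table: pd.DataFrame | None = None
    manifest: dict | None = None
    descriptor_table: pd.DataFrame | None = None
    split: dataset.SplitIndex | None = None
    encoder: dataset.Encoder | None = None
    encoded: pd.DataFrame | None = None
    selection: featsel.FeatureSelection | None = None
    features: list | None = None
    cv_result: modelling.CVResult | None = None
    model: modelling.TunedModel | None = None
    results: dict = field(default_factory=dict)

    @property
    def train(self) -> pd.DataFrame:
        return self.encoded.loc[self.split.train_ids]

    @property
    def test(self) -> pd.DataFrame:
        return self.encoded.loc[self.split.test_ids]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "PipelineState":
        return joblib.load(path)


def _energy_model(config: RunConfig):
    return LennardJonesModel() if config.energy_model == "lj" else MorseModel()


def _outdir(config: RunConfig) -> Path | None:
    if config.out_dir is None:
        return None
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# stages

def stage_data(state: PipelineState) -> PipelineState:
    """Load the viability CSV, or simulate the default scenario."""
    cfg = state.config
    if cfg.dataset_csv is not None:
        state.table = dataset.read_viability_csv(cfg.dataset_csv)
        state.manifest = {"source": str(cfg.dataset_csv)}
    else:
        scenario = synthdata.SimScenario(seed=cfg.seed)
        state.table, state.manifest = synthdata.simulate_viability(scenario)
    out = _outdir(cfg)
    if out:
        state.table.to_csv(out / "dataset.csv", index=False)
    return state


def build_particles(state: PipelineState) -> dict:
    """Carve one proxy particle per distinct (phase, core diameter)."""
    cfg = state.config
    if cfg.cif_dir is not None:
        cif_dir = Path(cfg.cif_dir)
    else:
        out = _outdir(cfg)
        if out is None:
            import tempfile

            out = Path(tempfile.mkdtemp(prefix="nanoqstr_"))
        cif_dir = out / "cifs"
        synthdata.make_toy_cifs(cif_dir)
    cells = {}
    for path in sorted(cif_dir.glob("*.cif")):
        phase = path.stem.split("_")[0]
        cells[phase] = crystal.parse_cif(path.read_text(), phase_id=phase)

    particles = {}
    pairs = state.table[["phase", "core_diameter"]].drop_duplicates().itertuples(index=False)
    for phase, diam_nm in pairs:
        if phase not in cells:
            raise ValidationError(f"no CIF found for phase {phase!r} in {cif_dir}")
        diameter_ang = diam_nm * cfg.scale_ang_per_nm
        particles[(phase, float(diam_nm))] = crystal.carve_sphere(
            cells[phase], diameter_ang,
            center_policy=cfg.center_policy, shell_depth=cfg.shell_depth,
        )
    return {"cells": cells, "particles": particles}


def stage_descriptors(state: PipelineState) -> PipelineState:
    """Compute the 57-descriptor table for every particle in the dataset."""
    cfg = state.config
    built = build_particles(state)
    model = _energy_model(cfg)
    # bulk lattice energies depend only on the phase: compute once
    bulk_cache = {p: model.bulk_energy_per_atom(c) for p, c in built["cells"].items()}

    class _CachedBulk:
        def __init__(self, inner, bulk):
            self._inner, self._bulk = inner, bulk

        def per_atom_energy(self, positions, species):
            return self._inner.per_atom_energy(positions, species)

        def bulk_energy_per_atom(self, cell):
            return self._bulk[cell.phase_id]

    cached = _CachedBulk(model, bulk_cache)
    rows = []
    for (phase, diam_nm), particle in built["particles"].items():
        t0 = time.time()
        vec = descriptors.compute_descriptor_vector(particle, built["cells"][phase], cached)
        row = {"phase": phase, "diameter_nm": diam_nm, "n_atoms": particle.n_atoms}
        row.update(vec.values)
        row["missing_flags"] = ";".join(sorted(vec.missing)) if vec.missing else ""
        rows.append(row)
        log.info("descriptors %s %.1f nm: %d atoms in %.2fs",
                 phase, diam_nm, particle.n_atoms, time.time() - t0)
    state.descriptor_table = pd.DataFrame(rows)
    out = _outdir(cfg)
    if out:
        state.descriptor_table.to_csv(out / "descriptors.csv", index=False)
    return state


def stage_curate(state: PipelineState) -> PipelineState:
    """Label, split, encode on training statistics, and join descriptors."""
    cfg = state.config
    table = state.table.copy()
    table["cytotoxic"] = dataset.label_cytotoxicity(table["viability"])
    state.split = dataset.stratified_split(table, test_frac=cfg.test_frac, seed=cfg.seed)

    raw_train = table.loc[state.split.train_ids]
    work = raw_train.copy()
    work["coating_group"] = work.get("coating", pd.Series(index=work.index)).map(dataset.coating_group)
    state.encoder = dataset.Encoder().fit(work)
    encoded = state.encoder.transform(table)

    if cfg.approach == "atomistic":
        if state.descriptor_table is None:
            stage_descriptors(state)
        encoded = dataset.join_descriptors(encoded, state.descriptor_table)
    state.encoded = encoded
    out = _outdir(cfg)
    if out:
        (out / "encoding.json").write_text(state.encoder.to_json())
        encoded.to_csv(out / "curated.csv", index=False)
    return state


def stage_features(state: PipelineState) -> PipelineState:
    """Fix the modelling feature list for the chosen approach."""
    cfg = state.config
    if cfg.approach == "evidence":
        state.features = [c for c in EVIDENCE_FEATURES if c in state.encoded.columns]
        state.selection = None
        return state
    train = state.train
    atom_cols = [
        c for c in state.encoded.columns
        if c.startswith("D") and c[1:].isdigit() and not train[c].isna().any()
    ]
    state.selection = featsel.shap_rank_select(
        train, target="viability", atomistic_features=atom_cols,
        k=cfg.k_top, seed=cfg.seed,
    )
    state.features = state.selection.final_set
    out = _outdir(cfg)
    if out:
        (out / "selection.json").write_text(json.dumps(state.selection.to_dict(), indent=1))
    return state


def stage_model(state: PipelineState) -> PipelineState:
    """Nested-CV comparison of the algorithm pool and final refit."""
    cfg = state.config
    specs = modelling.default_model_specs(cfg.algorithms)
    state.cv_result = modelling.nested_cv(
        state.train, state.features, "viability",
        specs=specs, n_draws=cfg.n_draws, seed=cfg.seed,
    )
    winner = next(s for s in specs if s.algorithm_id == state.cv_result.winner)
    state.model = modelling.fit_final(
        state.train, state.features, "viability",
        winner, state.cv_result.best_params[winner.algorithm_id], seed=cfg.seed,
    )
    state.results["cv"] = state.cv_result.to_dict()
    state.results["metrics"] = {
        "train": modelling.regression_metrics(
            state.train["viability"], state.model.predict(state.train), p=len(state.features)
        ),
        "test": modelling.regression_metrics(
            state.test["viability"], state.model.predict(state.test), p=len(state.features)
        ),
    }
    out = _outdir(cfg)
    if out:
        joblib.dump(state.model, out / "model.joblib")
    return state


def _winner_spec(state: PipelineState):
    specs = modelling.default_model_specs(state.config.algorithms)
    spec = next(s for s in specs if s.algorithm_id == state.cv_result.winner)
    return spec, state.cv_result.best_params[spec.algorithm_id]


def stage_validate(state: PipelineState) -> PipelineState:
    """LOO Q², Golbraikh–Tropsha flags, y-scrambling and bootstrap CIs."""
    cfg = state.config
    spec, params = _winner_spec(state)
    q2 = validation.loo_q2(state.train, state.features, "viability", spec, params, seed=cfg.seed)
    gt = validation.golbraikh_tropsha(
        state.test["viability"], state.model.predict(state.test), q2_loo=q2
    )
    scramble = validation.y_scramble(
        state.train, state.test, state.features, "viability", spec, params,
        n_rounds=cfg.scramble_rounds, seed=cfg.seed,
    )
    boot = validation.bootstrap_ci(
        state.train, state.features, "viability", spec, params,
        B=cfg.bootstrap_B, seed=cfg.seed,
    )
    state.results["validation"] = {
        "q2_loo": q2,
        "golbraikh_tropsha": gt.to_dict(),
        "y_scramble": scramble,
        "bootstrap": boot,
    }
    return state


def stage_apd(state: PipelineState) -> PipelineState:
    """Fit both applicability domains and gate the test set."""
    cfg = state.config
    cats = [c for c in APD_CATEGORICAL if c in state.features]
    train_feats = state.train[state.features]
    euclid = apd_mod.fit_apd(train_feats, metric="euclidean", Z=cfg.apd_z,
                             categorical_columns=cats)
    weights = None
    if state.results.get("explanation"):
        weights = dict(state.results["explanation"]["global_ranking"])
    else:
        exp = explain.shap_summary(state.model, state.train, seed=cfg.seed)
        weights = dict(zip(exp.global_table["feature"], exp.global_table["mean_abs_shap"]))
    gower = apd_mod.fit_apd(train_feats, metric="gower", Z=cfg.apd_z,
                            categorical_columns=cats, weights=weights)
    test_feats = state.test[state.features]
    state.results["apd"] = {
        "euclidean": {**euclid.to_dict(),
                      "test_in_domain_fraction": float(euclid.in_domain(test_feats)["reliable"].mean())},
        "gower": {**gower.to_dict(),
                  "test_in_domain_fraction": float(gower.in_domain(test_feats)["reliable"].mean())},
    }
    state.results["apd_models"] = {"euclidean": euclid, "gower": gower}
    return state


def stage_explain(state: PipelineState) -> PipelineState:
    """Global/local SHAP, permutation importance, curves and waterfalls."""
    cfg = state.config
    spec, params = _winner_spec(state)
    exp = explain.shap_summary(state.model, state.encoded, background=state.train, seed=cfg.seed)
    perm = explain.permutation_importance(
        state.model, state.encoded, n_repeats=cfg.n_permutation_repeats, seed=cfg.seed
    )
    ranked = list(exp.global_table["feature"])
    curve = explain.feature_addition_curve(
        state.train, state.test, ranked, "viability", spec, params, seed=cfg.seed
    )
    pdp_conc = explain.pdp_ice(state.model, state.encoded, "concentration", centred=True)
    pdp_2d = explain.pdp_ice(state.model, state.encoded, ("concentration", "core_diameter"))
    waterfalls = [
        explain.waterfall_export(state.model, state.test.iloc[[i]], background=state.train,
                                 seed=cfg.seed)
        for i in range(min(2, len(state.test)))
    ]
    state.results["explanation"] = {
        "global_ranking": [(f, float(s)) for f, s in
                           zip(exp.global_table["feature"], exp.global_table["mean_abs_shap"])],
        "permutation_ranking": [(f, float(s)) for f, s in
                                zip(perm["feature"], perm["importance_mean"])],
        "feature_addition": curve.to_dict(orient="list"),
        "pdp_concentration": {"grid": pdp_conc["grid"].tolist(),
                              "pdp": pdp_conc["pdp"].tolist()},
        "pdp_2d_features": list(pdp_2d["features"]),
        "waterfalls": waterfalls,
    }
    out = _outdir(cfg)
    if out:
        exp.global_table.to_csv(out / "shap_global.csv", index=False)
        perm.to_csv(out / "permutation_importance.csv", index=False)
        curve.to_csv(out / "feature_addition.csv", index=False)
    return state


def stage_report(state: PipelineState) -> PipelineState:
    from .report import generate_report

    text = generate_report(state)
    state.results["report"] = text
    out = _outdir(state.config)
    if out:
        (out / "report.md").write_text(text)
        serialisable = {k: v for k, v in state.results.items()
                        if k not in ("report", "apd_models")}
        (out / "results.json").write_text(json.dumps(serialisable, indent=1, default=str))
    return state


_STAGES = [
    ("data", stage_data),
    ("curate", stage_curate),
    ("features", stage_features),
    ("model", stage_model),
    ("validate", stage_validate),
    ("apd", stage_apd),
    ("explain", stage_explain),
    ("report", stage_report),
]


def run_pipeline(config: RunConfig) -> PipelineState:
    """Execute every stage in order and return the populated state.

    The evidence approach skips particle construction and descriptor
    computation entirely (stage_curate only joins descriptors for the
    atomistic approach).
    """
    state = PipelineState(config=config)
    for name, fn in _STAGES:
        t0 = time.time()
        fn(state)
        log.info("stage %-9s done in %.1fs", name, time.time() - t0)
    out = _outdir(config)
    if out:
        state.save(out / "state.joblib")
    return state
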