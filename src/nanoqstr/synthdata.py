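"""Synthetic fixtures: toy crystal structures and a simulated viability table.

The simulated dose-response table reproduces the statistical structure the
analysis pipeline assumes: 186 treatment rows from a handful of "studies",
iron-carbide core phases with diameters spanning 4.9-44.3 nm, a log-spaced
concentration ladder, coating-modulated Hill-type dose response with
Gaussian measurement noise, and roughly 18 % of rows below the 70 %
cytotoxicity threshold.  Every generating parameter is recorded in a
manifest so feature-importance recovery is checkable.

The CIF files written here are *synthetic* minimal cells (simple cubic,
fcc, and toy two-species Fe/C cells with the right stoichiometries); they
are stand-ins for real crystallographic database entries and are labelled
as such in their file names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CYTOTOXIC_THRESHOLD, coating_group

#: Coating label pool cycled over experiments; groups are derived from the
#: free text by the dataset module, multipliers by the generator.
_COATINGS = [
    "none", "PEG", "bovine serum albumin", "poly(acrylic) acid", "citrate",
    "pluronic acid", "none", "transferrin", "dextran", "oleic acid",
]

_CELL_LINES = {
    # cell line: (organism, health status)
    "MCF-7": ("human", "cancer"),
    "HeLa": ("human", "cancer"),
    "A549": ("human", "cancer"),
    "HepG2": ("human", "cancer"),
    "BEAS-2B": ("human", "normal"),
    "RAW264.7": ("murine", "normal"),
    "L929": ("murine", "normal"),
}

_SHELLS = ["iron oxide", "carbon", "silica", "none", "MnO2"]

#: Default particle inventory: (phase, core diameter nm) spanning the
#: in-domain size range 4.9-44.3 nm across the three carbide phases.
DEFAULT_PARTICLES = [
    ("Fe2C", 4.9), ("Fe2C", 10.2), ("Fe2C", 18.7), ("Fe2C", 27.5),
    ("Fe3C", 6.3), ("Fe3C", 14.0), ("Fe3C", 22.1), ("Fe3C", 35.6),
    ("Fe5C2", 8.1), ("Fe5C2", 16.4), ("Fe5C2", 28.9), ("Fe5C2", 44.3),
]

DEFAULT_DOSES = [3.125, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0]


@dataclass
class SimScenario:
    """Generating parameters of the simulated dose-response study."""

    n_rows: int = 186
    particles: list = field(default_factory=lambda: list(DEFAULT_PARTICLES))
    doses: list = field(default_factory=lambda: list(DEFAULT_DOSES))
    ic50_base: float = 200.0      # µg/mL for an uncoated 20 nm particle
    hill_slope: float = 1.3
    size_exponent: float = 0.2    # IC50 ∝ (diameter / 20 nm)^γ
    coating_multipliers: dict = field(
        default_factory=lambda: {
            "bare": 0.55, "polymer-based": 1.8, "protein-based": 1.25, "other": 1.0,
        }
    )
    noise_sd: float = 0.05
    cytotoxic_fraction_target: float = 0.183
    seed: int = 7


def hill_viability(concentration, ic50_eff, hill_slope) -> np.ndarray:
    """Noise-free fraction-of-control viability: 1 / (1 + (C/IC50)^h)."""
    c = np.asarray(concentration, dtype=float)
    return 1.0 / (1.0 + (c / ic50_eff) ** hill_slope)


def effective_ic50(scenario: SimScenario, group: str, diameter_nm: float) -> float:
    mult = scenario.coating_multipliers[group]
    return scenario.ic50_base * mult * (diameter_nm / 20.0) ** scenario.size_exponent


def simulate_viability(scenario: SimScenario | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate the treatment table; returns (table, ground-truth manifest).

    Experiments cycle over (particle, coating, cell line) combinations,
    each contributing one full concentration ladder, until ``n_rows`` rows
    exist (the last experiment may be truncated).  Deterministic under the
    scenario seed; identical scenarios give byte-identical CSV output.
    """
    sc = scenario or SimScenario()
    rng = np.random.default_rng(sc.seed)
    lines = list(_CELL_LINES)
    rows = []
    exp_idx = 0
    while len(rows) < sc.n_rows:
        phase, diam = sc.particles[exp_idx % len(sc.particles)]
        coating = _COATINGS[exp_idx % len(_COATINGS)]
        cell_line = lines[(exp_idx // 2) % len(lines)]
        shell = _SHELLS[exp_idx % len(_SHELLS)]
        organism, health = _CELL_LINES[cell_line]
        group = coating_group(coating)
        ic50 = effective_ic50(sc, group, diam)
        shell_thickness = 0.0 if shell == "none" else float(
            np.round(rng.normal(2.25, 0.25), 2)
        )
        size_sd = float(np.round(0.1 * diam * abs(1 + 0.3 * rng.standard_normal()), 2))
        for dose in sc.doses:
            if len(rows) >= sc.n_rows:
                break
            v = float(hill_viability(dose, ic50, sc.hill_slope))
            v = max(0.0, v + float(rng.normal(0.0, sc.noise_sd)))
            rows.append(
                {
                    "experiment_id": f"EXP{exp_idx:03d}",
                    "phase": phase,
                    "core_diameter": diam,
                    "size_sd": size_sd,
                    "shell_material": shell,
                    "shell_thickness": shell_thickness,
                    "coating": coating,
                    "concentration": dose,
                    "cell_line": cell_line,
                    "organism": organism,
                    "health_status": health,
                    "viability": round(v, 4),
                }
            )
        exp_idx += 1

    table = pd.DataFrame(rows)
    achieved = float((table["viability"] < CYTOTOXIC_THRESHOLD).mean())
    if abs(achieved - sc.cytotoxic_fraction_target) > 0.05:
        warnings.warn(
            f"achieved cytotoxic fraction {achieved:.3f} differs from the "
            f"target {sc.cytotoxic_fraction_target:.3f} by more than 5 points",
            stacklevel=2,
        )
    manifest = {
        "seed": sc.seed,
        "n_rows": sc.n_rows,
        "ic50_base": sc.ic50_base,
        "hill_slope": sc.hill_slope,
        "size_exponent": sc.size_exponent,
        "coating_multipliers": dict(sc.coating_multipliers),
        "noise_sd": sc.noise_sd,
        "achieved_cytotoxic_fraction": achieved,
        "driving_features": ["concentration", "coating_group", "core_diameter"],
    }
    return table, manifest


# ---------------------------------------------------------------------------
# toy CIFs

_TOY_CIFS = {
    # synthetic minimal cells; NOT real crystallographic database entries
    "sc": """data_sc_toy
_cell_length_a 2.5
_cell_length_b 2.5
_cell_length_c 2.5
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
Fe1 0.0 0.0 0.0
""",
    "fcc": """data_fcc_toy
_cell_length_a 3.6
_cell_length_b 3.6
_cell_length_c 3.6
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
Fe1 0.0 0.0 0.0
Fe2 0.5 0.5 0.0
Fe3 0.5 0.0 0.5
Fe4 0.0 0.5 0.5
""",
    "Fe2C": """data_Fe2C_toy
_cell_length_a 4.0
_cell_length_b 4.0
_cell_length_c 4.4
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
Fe1 Fe 0.0 0.0 0.0
Fe2 Fe 0.5 0.5 0.5
C1 C 0.0 0.5 0.25
""",
    "Fe3C": """data_Fe3C_toy
_cell_length_a 3.8
_cell_length_b 3.8
_cell_length_c 3.8
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
Fe1 Fe 0.0 0.0 0.0
Fe2 Fe 0.5 0.5 0.0
Fe3 Fe 0.5 0.0 0.5
C1 C 0.0 0.5 0.5
""",
    "Fe5C2": """data_Fe5C2_toy
_cell_length_a 4.6
_cell_length_b 4.6
_cell_length_c 4.6
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
Fe1 Fe 0.0 0.0 0.0
Fe2 Fe 0.5 0.5 0.0
Fe3 Fe 0.5 0.0 0.5
Fe4 Fe 0.0 0.5 0.5
Fe5 Fe 0.5 0.5 0.5
C1 C 0.25 0.25 0.25
C2 C 0.75 0.75 0.75
""",
}


def toy_cif_text(name: str) -> str:
    """CIF text of one synthetic toy cell (sc, fcc, Fe2C, Fe3C, Fe5C2)."""
    return _TOY_CIFS[name]


def make_toy_cifs(out_dir) -> dict[str, Path]:
    """Write the synthetic toy CIFs to ``out_dir``; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, text in _TOY_CIFS.items():
        path = out / f"{name}_toy_synthetic.cif"
        path.write_text(text)
        paths[name] = path
    return paths
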