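"""Atom-level nanoparticle descriptors.

Fifty-seven descriptors characterise each particle: atom counts, potential
and lattice energies, coordination numbers at 3/4/5 Å cutoffs, a
species-resolved bonded-coordination variant, bond-orientational
("hexatic") order parameters, and sphere geometry — each evaluated for the
whole particle, the core, and the shell, plus core-shell differences and
ratios.  Eight ids are fixed by convention and used downstream verbatim:

====  =======================================================
D5    average potential energy of the core atoms (eV)
D7    core - shell average potential energy difference (eV)
D15   average coordination parameter (3 Å) of the core atoms
D21   average coordination parameter (4 Å) of the shell atoms
D32   lattice energy of the particle (eV/atom)
D33   bulk lattice energy - particle lattice energy (eV/atom)
D46   average second hexatic order parameter (q6) of all atoms
D48   average second hexatic order parameter (q6) of the shell
====  =======================================================

"Second hexatic order parameter" is read as the l=6 Steinhardt
bond-orientational invariant (with l=4 as the first); a planar psi_6
variant is computed alongside.  Undefined entries (e.g. core averages of
an all-shell particle) are flagged as missing, never silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .crystal import Nanoparticle, UnitCell
from .energy import EnergyModel
from .errors import ConfigurationError, MissingRegionError, ValidationError

#: Covalent radii (Å, Cordero 2008) for the bonded-coordination variant.
COVALENT_RADII = {"Fe": 1.32, "C": 0.76, "O": 0.66, "Si": 1.11, "Mn": 1.39}

TABLE_IDS = ("D5", "D7", "D15", "D21", "D32", "D33", "D46", "D48")


@dataclass(frozen=True)
class NeighborSpec:
    """Inclusive distance-cutoff neighbour rule (self excluded)."""

    cutoff: float

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValidationError(f"cutoff must be positive, got {self.cutoff}")


@dataclass(frozen=True)
class BondOrderSpec:
    """Order ``l`` of the bond-orientational invariant and its neighbour rule."""

    l: int = 6
    cutoff: float = 4.0
    variant: str = "steinhardt"  # or "planar"

    def __post_init__(self):
        if self.l < 1:
            raise ValidationError(f"harmonic order must be >= 1, got {self.l}")


# ---------------------------------------------------------------------------
# neighbour counting

def neighbor_counts(np_: Nanoparticle, spec: NeighborSpec | float) -> np.ndarray:
    """Per-atom neighbour counts within the cutoff (inclusive boundary)."""
    cutoff = spec.cutoff if isinstance(spec, NeighborSpec) else float(spec)
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    n = np_.n_atoms
    counts = np.zeros(n, dtype=int)
    if n < 2:
        return counts
    tree = cKDTree(np_.positions)
    pairs = tree.query_pairs(cutoff * (1 + 1e-12), output_type="ndarray")
    if len(pairs):
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    return counts


def bonded_neighbor_counts(np_: Nanoparticle, scale: float = 1.2) -> np.ndarray:
    """Unlike-species neighbour counts with cutoff ``scale * (r_cov_i + r_cov_j)``.

    Mirrors the species-pair coordination rule whose cutoff can undershoot
    the actual bond lengths and return zeros.
    """
    n = np_.n_atoms
    counts = np.zeros(n, dtype=int)
    if n < 2:
        return counts
    radii = np.array([COVALENT_RADII.get(s, 1.2) for s in np_.species])
    max_cut = scale * 2 * radii.max()
    tree = cKDTree(np_.positions)
    pairs = tree.query_pairs(max_cut, output_type="ndarray")
    if not len(pairs):
        return counts
    i, j = pairs[:, 0], pairs[:, 1]
    species = np.asarray(np_.species, dtype=object)
    unlike = species[i] != species[j]
    r = np.linalg.norm(np_.positions[i] - np_.positions[j], axis=1)
    within = r <= scale * (radii[i] + radii[j])
    sel = unlike & within
    np.add.at(counts, i[sel], 1)
    np.add.at(counts, j[sel], 1)
    return counts


def coordination_descriptor(np_: Nanoparticle, cutoff: float, region: str = "all") -> float:
    """Mean neighbour count over the region (neighbours counted against all atoms)."""
    mask = np_.region_mask(region)
    if not mask.any():
        raise MissingRegionError(f"region {region!r} is empty")
    return float(neighbor_counts(np_, cutoff)[mask].mean())


# ---------------------------------------------------------------------------
# bond-orientational order

def _neighbor_vectors(np_: Nanoparticle, cutoff: float):
    """For each atom, unit vectors to its neighbours (flat arrays + owner index)."""
    tree = cKDTree(np_.positions)
    pairs = tree.query_pairs(cutoff * (1 + 1e-12), output_type="ndarray")
    if not len(pairs):
        return np.empty(0, dtype=int), np.empty((0, 3))
    i, j = pairs[:, 0], pairs[:, 1]
    vec = np_.positions[j] - np_.positions[i]
    owners = np.concatenate([i, j])
    vectors = np.concatenate([vec, -vec])
    vectors = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    return owners, vectors


def steinhardt_q(np_: Nanoparticle, l: int = 6, cutoff: float = 4.0) -> np.ndarray:
    """Per-atom Steinhardt invariant ``q_l`` in [0, 1]; 0 for isolated atoms."""
    n = np_.n_atoms
    owners, vectors = _neighbor_vectors(np_, cutoff)
    q = np.zeros(n)
    if len(owners) == 0:
        return q
    theta = np.arccos(np.clip(vectors[:, 2], -1.0, 1.0))
    phi = np.arctan2(vectors[:, 1], vectors[:, 0])
    counts = np.bincount(owners, minlength=n).astype(float)
    has = counts > 0
    acc = np.zeros(n)
    for m in range(-l, l + 1):
        ylm = sph_harm_y(l, m, theta, phi)
        mean_re = np.bincount(owners, weights=ylm.real, minlength=n)
        mean_im = np.bincount(owners, weights=ylm.imag, minlength=n)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_re = np.where(has, mean_re / counts, 0.0)
            mean_im = np.where(has, mean_im / counts, 0.0)
        acc += mean_re**2 + mean_im**2
    q[has] = np.sqrt(4 * np.pi / (2 * l + 1) * acc[has])
    return q


def planar_psi(np_: Nanoparticle, l: int = 6, cutoff: float = 4.0) -> np.ndarray:
    """Planar bond-orientational parameter ``psi_l = |<exp(i l theta)>|`` (xy-plane)."""
    n = np_.n_atoms
    owners, vectors = _neighbor_vectors(np_, cutoff)
    psi = np.zeros(n)
    if len(owners) == 0:
        return psi
    theta = np.arctan2(vectors[:, 1], vectors[:, 0])
    counts = np.bincount(owners, minlength=n).astype(float)
    has = counts > 0
    re = np.bincount(owners, weights=np.cos(l * theta), minlength=n)
    im = np.bincount(owners, weights=np.sin(l * theta), minlength=n)
    psi[has] = np.hypot(re[has], im[has]) / counts[has]
    return psi


def bond_order_descriptor(np_: Nanoparticle, spec: BondOrderSpec, region: str = "all") -> float:
    """Region average of the per-atom order parameter chosen by ``spec``."""
    mask = np_.region_mask(region)
    if not mask.any():
        raise MissingRegionError(f"region {region!r} is empty")
    per_atom = (
        steinhardt_q(np_, spec.l, spec.cutoff)
        if spec.variant == "steinhardt"
        else planar_psi(np_, spec.l, spec.cutoff)
    )
    return float(per_atom[mask].mean())


# ---------------------------------------------------------------------------
# energy statistics

def energy_statistics(np_: Nanoparticle, model: EnergyModel) -> dict:
    """Average potential energies per region and the core-shell difference (eV)."""
    per_atom = model.per_atom_energy(np_.positions, np_.species)
    out = {}
    for region in ("all", "core", "shell"):
        mask = np_.region_mask(region)
        out[f"avg_pe_{region}"] = float(per_atom[mask].mean()) if mask.any() else None
    core, shell = out["avg_pe_core"], out["avg_pe_shell"]
    out["pe_core_minus_shell"] = None if core is None or shell is None else core - shell
    out["pe_core_over_shell"] = (
        None if core is None or shell is None or shell == 0 else core / shell
    )
    out["total_pe"] = float(per_atom.sum())
    return out


def lattice_energy_descriptors(np_: Nanoparticle, cell: UnitCell, model: EnergyModel) -> dict:
    """Particle and bulk lattice energies (eV per atom) and their difference."""
    total = float(model.per_atom_energy(np_.positions, np_.species).sum())
    np_lattice = total / np_.n_atoms
    bulk = float(model.bulk_energy_per_atom(cell))
    return {
        "np_lattice_energy": np_lattice,
        "bulk_lattice_energy": bulk,
        "bulk_minus_np": bulk - np_lattice,
        "np_over_bulk": np_lattice / bulk if bulk != 0 else None,
    }


# ---------------------------------------------------------------------------
# geometry

def geometry_descriptors(np_: Nanoparticle) -> dict:
    """Counts, nominal sphere volume/area and derived ratios."""
    if np_.n_atoms < 1:
        raise ValidationError("empty particle")
    r = np_.nominal_diameter / 2.0
    n_core = int((np_.region == "core").sum())
    n_shell = int((np_.region == "shell").sum())
    volume = 4.0 / 3.0 * math.pi * r**3
    area = 4.0 * math.pi * r**2
    return {
        "n_atoms": np_.n_atoms,
        "n_core": n_core,
        "n_shell": n_shell,
        "volume": volume,
        "surface_area": area,
        "surface_to_volume": area / volume,
        "core_shell_count_ratio": n_core / n_shell if (n_shell and n_core) else None,
        "core_fraction": n_core / np_.n_atoms,
        "shell_fraction": n_shell / np_.n_atoms,
        "surface_density": n_shell / area,
        "volume_density": np_.n_atoms / volume,
        "nominal_diameter": np_.nominal_diameter,
    }


# ---------------------------------------------------------------------------
# registry and vector assembly

@dataclass(frozen=True)
class DescriptorDef:
    """One registry entry: id, human-readable name, quantity key and units."""

    id: str
    name: str
    quantity: str  # key understood by compute_descriptor_vector
    region: str = "all"
    units: str = ""
    params: dict = field(default_factory=dict)


def _family(start, quantity, units, params=None, what=""):
    """all/core/shell/difference/ratio block of five consecutive ids."""
    params = params or {}
    ids = [f"D{start + i}" for i in range(5)]
    return [
        DescriptorDef(ids[0], f"average {what} of all atoms", quantity, "all", units, params),
        DescriptorDef(ids[1], f"average {what} of the core atoms", quantity, "core", units, params),
        DescriptorDef(ids[2], f"average {what} of the shell atoms", quantity, "shell", units, params),
        DescriptorDef(ids[3], f"core - shell difference of {what}", quantity, "difference", units, params),
        DescriptorDef(ids[4], f"core / shell ratio of {what}", quantity, "ratio", units, params),
    ]


def default_registry() -> list[DescriptorDef]:
    """The default 57-descriptor registry; layout is configuration, not code."""
    reg: list[DescriptorDef] = [
        DescriptorDef("D1", "number of atoms in the particle", "count", "all", "atoms"),
        DescriptorDef("D2", "number of core atoms", "count", "core", "atoms"),
        DescriptorDef("D3", "number of shell atoms", "count", "shell", "atoms"),
        DescriptorDef("D4", "average potential energy of all atoms", "avg_pe", "all", "eV"),
        DescriptorDef("D5", "average potential energy of the core atoms", "avg_pe", "core", "eV"),
        DescriptorDef("D6", "average potential energy of the shell atoms", "avg_pe", "shell", "eV"),
        DescriptorDef("D7", "core - shell average potential energy difference", "avg_pe", "difference", "eV"),
        DescriptorDef("D8", "core / shell average potential energy ratio", "avg_pe", "ratio", ""),
    ]
    reg += _family(9, "bonded_coordination", "atoms", {"scale": 1.2},
                   "bonded (unlike-species) coordination")
    for cutoff, start in ((3.0, 14), (4.0, 19), (5.0, 24)):
        reg += _family(start, "coordination", "atoms", {"cutoff": cutoff},
                       f"coordination parameter ({cutoff:g} Å)")
    reg += [
        DescriptorDef("D29", "total potential energy of the particle", "total_pe", "all", "eV"),
        DescriptorDef("D30", "shell atoms per unit surface area", "surface_density", "all", "1/Å²"),
        DescriptorDef("D31", "atoms per unit volume", "volume_density", "all", "1/Å³"),
        DescriptorDef("D32", "lattice energy of the particle", "np_lattice_energy", "all", "eV"),
        DescriptorDef("D33", "bulk lattice energy minus particle lattice energy", "bulk_minus_np", "all", "eV"),
        DescriptorDef("D34", "bulk lattice energy", "bulk_lattice_energy", "all", "eV"),
        DescriptorDef("D35", "particle / bulk lattice energy ratio", "np_over_bulk", "all", ""),
    ]
    reg += _family(36, "bond_order", "", {"l": 4, "variant": "steinhardt"},
                   "first hexatic order parameter (q4)")
    reg += _family(41, "bond_order", "", {"l": 6, "variant": "planar"},
                   "planar hexatic order parameter (psi6)")
    reg += _family(46, "bond_order", "", {"l": 6, "variant": "steinhardt"},
                   "second hexatic order parameter (q6)")
    reg += [
        DescriptorDef("D51", "particle volume", "volume", "all", "Å³"),
        DescriptorDef("D52", "particle surface area", "surface_area", "all", "Å²"),
        DescriptorDef("D53", "surface-to-volume ratio", "surface_to_volume", "all", "1/Å"),
        DescriptorDef("D54", "core / shell atom count ratio", "core_shell_count_ratio", "all", ""),
        DescriptorDef("D55", "core atom fraction", "core_fraction", "all", ""),
        DescriptorDef("D56", "nominal particle diameter", "nominal_diameter", "all", "Å"),
        DescriptorDef("D57", "shell atom fraction", "shell_fraction", "all", ""),
    ]
    return reg


@dataclass
class DescriptorVector:
    """Ordered id -> value map with units and missing-value flags."""

    values: dict
    units: dict
    missing: dict  # id -> reason

    def __len__(self):
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array([np.nan if v is None else v for v in self.values.values()])


def _region_stats(per_atom: np.ndarray, np_: Nanoparticle) -> dict:
    out = {}
    for region in ("all", "core", "shell"):
        mask = np_.region_mask(region)
        out[region] = float(per_atom[mask].mean()) if mask.any() else None
    core, shell = out["core"], out["shell"]
    out["difference"] = None if core is None or shell is None else core - shell
    out["ratio"] = None if core is None or shell is None or shell == 0 else core / shell
    return out


def compute_descriptor_vector(
    np_: Nanoparticle,
    cell: UnitCell,
    model: EnergyModel,
    registry: list[DescriptorDef] | None = None,
) -> DescriptorVector:
    """Evaluate the full registry for one particle.

    Exactly 57 values in registry order; entries whose region is empty (or
    whose denominator vanishes) are flagged missing and carried as None.
    """
    registry = default_registry() if registry is None else list(registry)
    if len(registry) != 57:
        raise ConfigurationError(f"descriptor registry must have 57 entries, got {len(registry)}")
    ids = [d.id for d in registry]
    if len(set(ids)) != 57:
        raise ConfigurationError("descriptor ids must be unique")

    geom = geometry_descriptors(np_)
    energy = energy_statistics(np_, model)
    lattice = lattice_energy_descriptors(np_, cell, model)

    per_atom_cache: dict[tuple, dict] = {}

    def stats_for(quantity: str, params: dict) -> dict:
        key = (quantity, tuple(sorted(params.items())))
        if key not in per_atom_cache:
            if quantity == "coordination":
                per_atom = neighbor_counts(np_, params["cutoff"]).astype(float)
            elif quantity == "bonded_coordination":
                per_atom = bonded_neighbor_counts(np_, params.get("scale", 1.2)).astype(float)
            elif quantity == "bond_order":
                spec = BondOrderSpec(
                    l=params["l"],
                    cutoff=params.get("cutoff", 4.0),
                    variant=params.get("variant", "steinhardt"),
                )
                per_atom = (
                    steinhardt_q(np_, spec.l, spec.cutoff)
                    if spec.variant == "steinhardt"
                    else planar_psi(np_, spec.l, spec.cutoff)
                )
            else:
                raise ConfigurationError(f"unknown per-atom quantity {quantity!r}")
            per_atom_cache[key] = _region_stats(per_atom, np_)
        return per_atom_cache[key]

    values, units, missing = {}, {}, {}
    for d in registry:
        value: float | None
        if d.quantity == "count":
            value = {"all": geom["n_atoms"], "core": geom["n_core"], "shell": geom["n_shell"]}[d.region]
        elif d.quantity == "avg_pe":
            value = {
                "all": energy["avg_pe_all"],
                "core": energy["avg_pe_core"],
                "shell": energy["avg_pe_shell"],
                "difference": energy["pe_core_minus_shell"],
                "ratio": energy["pe_core_over_shell"],
            }[d.region]
        elif d.quantity == "total_pe":
            value = energy["total_pe"]
        elif d.quantity in lattice:
            value = lattice[d.quantity]
        elif d.quantity in geom:
            value = geom[d.quantity]
        elif d.quantity in ("coordination", "bonded_coordination", "bond_order"):
            value = stats_for(d.quantity, d.params)[d.region]
        else:
            raise ConfigurationError(f"unknown quantity {d.quantity!r} for {d.id}")
        if value is None:
            missing[d.id] = f"undefined for region {d.region!r} on this particle"
        values[d.id] = value
        units[d.id] = d.units
    return DescriptorVector(values=values, units=units, missing=missing)
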