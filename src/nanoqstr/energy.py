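"""Interatomic energy models behind the descriptor layer.

The descriptor operations only require the :class:`EnergyModel` contract:
per-atom potential energies for an isolated cluster, and a periodic
bulk energy per atom for the reference unit cell.  Production-grade
many-body potentials (EAM/MEAM engines, OpenKIM models) can be adapted to
this contract; the built-in models are classical pair potentials
(Lennard-Jones by default, Morse as an alternative) with per-species-pair
parameters, which are sufficient for the stability-flavoured descriptors
(average potential energies, core-shell differences, lattice energies).

Pair energies are half-assigned to each partner so that region-restricted
sums are well defined: ``E_i = 1/2 * sum_{j != i} phi(r_ij)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.spatial import cKDTree

from .crystal import UnitCell, _perpendicular_widths
from .errors import ConfigurationError


class EnergyModel(Protocol):
    """Contract every energy backend must satisfy."""

    def per_atom_energy(self, positions: np.ndarray, species: list[str]) -> np.ndarray:
        """Per-atom potential energies (eV) of an isolated cluster."""
        ...

    def bulk_energy_per_atom(self, cell: UnitCell) -> float:
        """Periodic (minimal-image) energy per atom of the unit cell (eV)."""
        ...


#: Reference pair parameters for the iron-carbide system: (epsilon eV, sigma Å)
#: for Lennard-Jones, (De eV, a 1/Å, r0 Å) for Morse.  Generic literature-style
#: magnitudes chosen for plausible cohesion ordering Fe-Fe > Fe-C > C-C.
DEFAULT_LJ_PARAMS = {
    ("Fe", "Fe"): (0.40, 2.30),
    ("Fe", "C"): (0.20, 1.90),
    ("C", "C"): (0.10, 3.00),
}

DEFAULT_MORSE_PARAMS = {
    ("Fe", "Fe"): (0.40, 1.40, 2.55),
    ("Fe", "C"): (0.25, 1.80, 2.05),
    ("C", "C"): (0.10, 1.70, 3.20),
}


def _pair_key(a: str, b: str):
    return (a, b) if (a, b)[0] <= (a, b)[1] else (b, a)


def _normalise_params(params: dict) -> dict:
    out = {}
    for (a, b), v in params.items():
        out[_pair_key(a, b)] = tuple(float(x) for x in v)
    return out


@dataclass
class PairPotential:
    """Base class: neighbour bookkeeping shared by LJ and Morse."""

    params: dict = field(default_factory=dict)
    cutoff: float = 8.0

    def __post_init__(self):
        self.params = _normalise_params(self.params)

    def _pair_params(self, a: str, b: str):
        key = _pair_key(a, b)
        try:
            return self.params[key]
        except KeyError:
            raise ConfigurationError(
                f"no pair parameters for species pair {key}"
            ) from None

    def pair_energy(self, r: np.ndarray, a: str, b: str) -> np.ndarray:
        raise NotImplementedError

    def per_atom_energy(self, positions, species) -> np.ndarray:
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        energies = np.zeros(n)
        if n < 2:
            return energies
        tree = cKDTree(positions)
        pairs = tree.query_pairs(self.cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return energies
        i, j = pairs[:, 0], pairs[:, 1]
        r = np.linalg.norm(positions[i] - positions[j], axis=1)
        species = list(species)
        # evaluate species pairs in groups
        keys = np.array([f"{_pair_key(species[a], species[b])}" for a, b in pairs])
        phi = np.empty(len(pairs))
        for key in np.unique(keys):
            m = keys == key
            a_idx = pairs[m][0]
            phi[m] = self.pair_energy(r[m], species[a_idx[0]], species[a_idx[1]])
        np.add.at(energies, i, 0.5 * phi)
        np.add.at(energies, j, 0.5 * phi)
        return energies

    def total_energy(self, positions, species) -> float:
        return float(self.per_atom_energy(positions, species).sum())

    def bulk_energy_per_atom(self, cell: UnitCell) -> float:
        """Energy per atom of the infinite crystal, by explicit image sums.

        Every atom of the central cell interacts with all periodic images
        within the cutoff; each pair energy is half-assigned as for
        clusters.
        """
        widths = _perpendicular_widths(cell.lattice)
        reach = np.ceil(self.cutoff / widths).astype(int)
        shifts = np.array(
            [
                (i, j, k)
                for i in range(-reach[0], reach[0] + 1)
                for j in range(-reach[1], reach[1] + 1)
                for k in range(-reach[2], reach[2] + 1)
            ],
            dtype=float,
        )
        base = cell.cartesian_sites()
        images = (shifts @ cell.lattice)[:, None, :] + base[None, :, :]
        images = images.reshape(-1, 3)
        image_species = list(cell.species) * len(shifts)
        central_idx = np.flatnonzero((shifts == 0).all(axis=1))[0] * cell.n_sites

        tree = cKDTree(images)
        total = 0.0
        for local, pos in enumerate(base):
            gi = central_idx + local
            neigh = tree.query_ball_point(pos, self.cutoff)
            neigh = [j for j in neigh if j != gi]
            if not neigh:
                continue
            r = np.linalg.norm(images[neigh] - pos, axis=1)
            for j_idx, rr in zip(neigh, r):
                total += 0.5 * float(
                    self.pair_energy(np.array([rr]), cell.species[local], image_species[j_idx])[0]
                )
        return total / cell.n_sites


@dataclass
class LennardJonesModel(PairPotential):
    """12-6 Lennard-Jones pair potential, untruncated up to ``cutoff``."""

    def __post_init__(self):
        if not self.params:
            self.params = dict(DEFAULT_LJ_PARAMS)
        super().__post_init__()

    def pair_energy(self, r, a, b):
        eps, sigma = self._pair_params(a, b)
        sr6 = (sigma / r) ** 6
        return 4.0 * eps * (sr6**2 - sr6)


@dataclass
class MorseModel(PairPotential):
    """Morse pair potential ``De*((1-exp(-a(r-r0)))^2 - 1)``."""

    def __post_init__(self):
        if not self.params:
            self.params = dict(DEFAULT_MORSE_PARAMS)
        super().__post_init__()

    def pair_energy(self, r, a, b):
        de, aa, r0 = self._pair_params(a, b)
        e = 1.0 - np.exp(-aa * (r - r0))
        return de * (e**2 - 1.0)


def reference_pair_energy(positions, species, params=None, cutoff: float = 8.0,
                          kind: str = "lj") -> np.ndarray:
    """Per-atom energies under the reference pair potential.

    Convenience wrapper used by tests and scripts; ``kind`` selects
    Lennard-Jones (default) or Morse.
    """
    cls = LennardJonesModel if kind == "lj" else MorseModel
    model = cls(params=params or {}, cutoff=cutoff)
    return model.per_atom_energy(positions, species)
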