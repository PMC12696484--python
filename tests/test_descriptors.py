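"""Neighbour counts, order parameters, energies and the 57-id registry."""

import numpy as np
import pytest

from nanoqstr import crystal, descriptors
from nanoqstr.descriptors import (
    BondOrderSpec, bond_order_descriptor, bonded_neighbor_counts,
    compute_descriptor_vector, coordination_descriptor, default_registry,
    energy_statistics, geometry_descriptors, lattice_energy_descriptors,
    neighbor_counts, planar_psi, steinhardt_q,
)
from nanoqstr.energy import LennardJonesModel
from nanoqstr.errors import ConfigurationError, MissingRegionError


def particle_from(positions, species=None, diameter=None, center=(0, 0, 0), depth=4.0):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    species = species or ["Fe"] * len(positions)
    diameter = diameter or 2 * np.linalg.norm(positions - np.asarray(center), axis=1).max() + 1e-6
    p = crystal.Nanoparticle(
        positions=positions, species=species,
        region=np.array(["shell"] * len(positions), dtype=object),
        nominal_diameter=diameter, center=np.asarray(center, dtype=float),
    )
    return crystal.partition_core_shell(p, depth)


@pytest.fixture()
def sc_lattice():
    """5x5x5 simple cubic lattice, a = 2.5 Å, centred on the origin."""
    g = np.arange(-2, 3) * 2.5
    pos = np.array([(x, y, z) for x in g for y in g for z in g])
    return particle_from(pos, diameter=25.0)


class TestNeighborCounts:
    def test_interior_sc_atom_counts(self, sc_lattice):
        center = np.flatnonzero((sc_lattice.positions == 0).all(axis=1))[0]
        assert neighbor_counts(sc_lattice, 3.0)[center] == 6
        assert neighbor_counts(sc_lattice, 4.0)[center] == 18  # 6 at 2.5 + 12 at 3.536

    def test_single_atom_has_no_neighbors(self):
        p = particle_from([[0, 0, 0]])
        assert neighbor_counts(p, 10.0).tolist() == [0]

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 10, size=(250, 3))
        p = particle_from(pos, center=pos.mean(axis=0))
        for cutoff in (1.5, 3.0, 6.0):
            brute = np.array([
                sum(
                    1 for j in range(len(pos))
                    if j != i and np.linalg.norm(pos[i] - pos[j]) <= cutoff
                )
                for i in range(len(pos))
            ])
            assert (neighbor_counts(p, cutoff) == brute).all()

    def test_monotone_in_cutoff(self, sc_lattice):
        c1 = neighbor_counts(sc_lattice, 3.0)
        c2 = neighbor_counts(sc_lattice, 4.5)
        assert (c2 >= c1).all()


class TestCoordination:
    def test_seven_atom_cubic_mean(self, seven_atom_particle):
        # cutoff 2.5 Å: only the six centre-vertex bonds -> (6 + 6*1)/7;
        # cutoff 3.0 Å also catches the twelve 2*sqrt(2) vertex-vertex
        # pairs -> (6 + 6*5)/7 (brute-force enumeration)
        assert coordination_descriptor(seven_atom_particle, 2.5, "all") == pytest.approx(12 / 7)
        assert coordination_descriptor(seven_atom_particle, 3.0, "all") == pytest.approx(36 / 7)

    def test_cutoff_below_spacing_gives_zero(self, seven_atom_particle):
        assert coordination_descriptor(seven_atom_particle, 1.0, "all") == 0.0

    def test_empty_core_raises(self, seven_atom_particle):
        with pytest.raises(MissingRegionError):
            coordination_descriptor(seven_atom_particle, 3.0, "core")

    def test_region_mean_counts_neighbors_from_all_atoms(self):
        # core atom at origin with 6 shell neighbours: its count is 6
        pos = np.vstack([[0, 0, 0], 2.0 * np.vstack([np.eye(3), -np.eye(3)])])
        p = particle_from(pos, diameter=10.0, depth=4.0)
        assert list(p.region).count("core") == 1
        assert coordination_descriptor(p, 3.0, "core") == 6.0


class TestBondOrder:
    def test_fcc_q6_closed_form(self):
        """12 ideal fcc neighbours give q6 = 0.5745 (brute-force reference)."""
        shell = []
        for a, b in ((0, 1), (1, 2), (0, 2)):
            for s1 in (1, -1):
                for s2 in (1, -1):
                    v = np.zeros(3)
                    v[a], v[b] = s1, s2
                    shell.append(v / np.sqrt(2) * 2.8)
        p = particle_from(np.vstack([[0, 0, 0], shell]), diameter=12.0)
        center = 0
        q6 = steinhardt_q(p, 6, cutoff=3.0)
        assert q6[center] == pytest.approx(0.5745, abs=1e-4)

    def test_planar_hexagon_psi6_is_one(self):
        angles = np.arange(6) * np.pi / 3
        ring = 2.5 * np.column_stack([np.cos(angles), np.sin(angles), np.zeros(6)])
        p = particle_from(np.vstack([[0, 0, 0], ring]), diameter=12.0)
        psi = planar_psi(p, 6, cutoff=3.0)
        assert psi[0] == pytest.approx(1.0, abs=1e-12)

    def test_isolated_atom_convention_is_zero(self):
        p = particle_from([[0, 0, 0]])
        assert steinhardt_q(p, 6, 4.0)[0] == 0.0
        assert planar_psi(p, 6, 4.0)[0] == 0.0

    def test_values_lie_in_unit_interval(self):
        rng = np.random.default_rng(11)
        p = particle_from(rng.uniform(0, 8, (60, 3)), center=(4, 4, 4))
        for arr in (steinhardt_q(p, 6, 4.0), steinhardt_q(p, 4, 4.0), planar_psi(p, 6, 4.0)):
            assert (arr >= 0).all() and (arr <= 1 + 1e-12).all()

    def test_random_gas_q6_below_fcc_value(self):
        rng = np.random.default_rng(5)
        p = particle_from(rng.uniform(0, 14, (300, 3)), center=(7, 7, 7))
        mean_q6 = bond_order_descriptor(p, BondOrderSpec(l=6, cutoff=4.0), "all")
        assert mean_q6 < 0.45  # well below the 0.5745 of a perfect fcc shell


class TestInvariance:
    def test_rigid_motion_leaves_descriptors_unchanged(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 8, (40, 3))
        p1 = particle_from(pos, center=pos.mean(axis=0))
        # random rotation (QR) + translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pos @ Q.T + np.array([5.0, -3.0, 2.0])
        p2 = particle_from(moved, center=moved.mean(axis=0))
        assert (neighbor_counts(p1, 4.0) == neighbor_counts(p2, 4.0)).all()
        assert steinhardt_q(p1, 6, 4.0) == pytest.approx(steinhardt_q(p2, 6, 4.0), abs=1e-8)


class _StubModel:
    """Energy model returning preset per-atom energies (for arithmetic tests)."""

    def __init__(self, energies, bulk=0.0):
        self.energies = np.asarray(energies, dtype=float)
        self.bulk = bulk

    def per_atom_energy(self, positions, species):
        return self.energies

    def bulk_energy_per_atom(self, cell):
        return self.bulk


class TestEnergyStatistics:
    def _two_region_particle(self):
        # 2 core atoms near the centre, 4 shell atoms near the surface
        pos = np.array([[0.5, 0, 0], [-0.5, 0, 0],
                        [7, 0, 0], [-7, 0, 0], [0, 7, 0], [0, -7, 0]])
        return particle_from(pos, diameter=16.0, depth=4.0)

    def test_core_shell_difference(self):
        p = self._two_region_particle()
        stats = energy_statistics(p, _StubModel([-2, -2, -1, -1, -1, -1]))
        assert stats["avg_pe_core"] == pytest.approx(-2.0)
        assert stats["pe_core_minus_shell"] == pytest.approx(-1.0)

    def test_equal_energies_have_zero_difference(self):
        p = self._two_region_particle()
        stats = energy_statistics(p, _StubModel([-1.5] * 6))
        assert stats["pe_core_minus_shell"] == pytest.approx(0.0)

    def test_lj_dimer_split_core_shell_difference_is_zero(self):
        r = 2 ** (1 / 6) * 2.3
        pos = np.array([[0.0, 0, 0], [r, 0, 0]])
        p = crystal.Nanoparticle(
            positions=pos, species=["Fe", "Fe"],
            region=np.array(["core", "shell"], dtype=object),
            nominal_diameter=2 * r + 1, center=pos[0],
        )
        model = LennardJonesModel(params={("Fe", "Fe"): (0.4, 2.3)}, cutoff=8.0)
        stats = energy_statistics(p, model)
        assert stats["pe_core_minus_shell"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle_on_cluster(self):
        rng = np.random.default_rng(9)
        g = np.arange(6) * 2.7
        pos = np.array([(x, y, z) for x in g for y in g for z in g])[:150]
        pos = pos + rng.uniform(-0.3, 0.3, size=pos.shape)
        p = particle_from(pos, center=pos.mean(axis=0), depth=2.0)
        model = LennardJonesModel(cutoff=5.0)
        per = model.per_atom_energy(p.positions, p.species)
        brute = np.zeros(len(pos))
        for i in range(len(pos)):
            for j in range(len(pos)):
                if i != j:
                    r = np.linalg.norm(pos[i] - pos[j])
                    if r <= 5.0:
                        brute[i] += 0.5 * model.pair_energy(np.array([r]), "Fe", "Fe")[0]
        assert np.abs(per - brute).max() < 1e-10
        stats = energy_statistics(p, model)
        core = p.region == "core"
        assert stats["avg_pe_core"] == pytest.approx(brute[core].mean(), abs=1e-10)


class TestLatticeEnergies:
    def test_identity_limit_gives_zero_difference(self):
        """A 'particle' of one isolated cell atom with no in-range images."""
        cell = crystal.UnitCell(np.eye(3) * 5.0, ["Fe"], np.zeros((1, 3)), "sc")
        p = particle_from([[0, 0, 0]])
        model = LennardJonesModel(params={("Fe", "Fe"): (0.4, 2.3)}, cutoff=2.0)
        out = lattice_energy_descriptors(p, cell, model)
        assert out["np_lattice_energy"] == 0.0
        assert out["bulk_minus_np"] == pytest.approx(0.0)

    def test_small_cluster_less_cohesive_than_bulk(self, seven_atom_particle):
        """Surface-dominated clusters sit above the bulk energy: D33 < 0."""
        cell = crystal.UnitCell(np.eye(3) * 2.0, ["Fe"], np.zeros((1, 3)), "sc")
        model = LennardJonesModel(params={("Fe", "Fe"): (0.4, 1.8)}, cutoff=5.0)
        out = lattice_energy_descriptors(seven_atom_particle, cell, model)
        assert out["bulk_lattice_energy"] < out["np_lattice_energy"] < 0
        assert out["bulk_minus_np"] < 0

    def test_single_atom_particle(self):
        cell = crystal.UnitCell(np.eye(3) * 2.6, ["Fe"], np.zeros((1, 3)), "sc")
        model = LennardJonesModel(params={("Fe", "Fe"): (0.4, 2.3)}, cutoff=5.0)
        p = particle_from([[0, 0, 0]])
        out = lattice_energy_descriptors(p, cell, model)
        assert out["np_lattice_energy"] == 0.0
        assert out["bulk_minus_np"] == pytest.approx(out["bulk_lattice_energy"])


class TestGeometry:
    def test_sphere_formulas(self):
        p = particle_from([[0, 0, 0]], diameter=10.0)
        g = geometry_descriptors(p)
        assert g["volume"] == pytest.approx(523.5987755982989)
        assert g["surface_area"] == pytest.approx(314.1592653589793)

    def test_all_shell_ratio_is_missing(self, seven_atom_particle):
        g = geometry_descriptors(seven_atom_particle)
        assert g["core_shell_count_ratio"] is None
        assert g["n_atoms"] == 7


class TestRegistryAndVector:
    def test_registry_has_57_unique_ids(self):
        reg = default_registry()
        assert len(reg) == 57
        assert len({d.id for d in reg}) == 57

    def test_wrong_registry_size_rejected(self, seven_atom_particle):
        cell = crystal.UnitCell(np.eye(3) * 2.0, ["Fe"], np.zeros((1, 3)), "sc")
        model = LennardJonesModel(params={("Fe", "Fe"): (0.4, 2.3)})
        with pytest.raises(ConfigurationError):
            compute_descriptor_vector(seven_atom_particle, cell, model,
                                      registry=default_registry()[:10])

    def test_anchored_ids_match_direct_calls(self, sc_cell):
        """D15/D21/D46/D48 equal the corresponding direct descriptor calls;
        D5/D7/D32/D33 equal the energy statistics."""
        model = LennardJonesModel(params={("Fe", "Fe"): (0.4, 2.3)}, cutoff=6.0)
        p = crystal.carve_sphere(sc_cell, 12.0, center_policy="atom", shell_depth=3.0)
        vec = compute_descriptor_vector(p, sc_cell, model).values
        assert vec["D15"] == pytest.approx(coordination_descriptor(p, 3.0, "core"))
        assert vec["D21"] == pytest.approx(coordination_descriptor(p, 4.0, "shell"))
        q6 = BondOrderSpec(l=6, cutoff=4.0)
        assert vec["D46"] == pytest.approx(bond_order_descriptor(p, q6, "all"))
        assert vec["D48"] == pytest.approx(bond_order_descriptor(p, q6, "shell"))
        stats = energy_statistics(p, model)
        assert vec["D5"] == pytest.approx(stats["avg_pe_core"])
        assert vec["D7"] == pytest.approx(stats["pe_core_minus_shell"])
        lat = lattice_energy_descriptors(p, sc_cell, model)
        assert vec["D32"] == pytest.approx(lat["np_lattice_energy"])
        assert vec["D33"] == pytest.approx(lat["bulk_minus_np"])

    def test_empty_core_flags_missing_not_zero(self, seven_atom_particle, sc_cell):
        model = LennardJonesModel(params={("Fe", "Fe"): (0.4, 2.3)})
        vec = compute_descriptor_vector(seven_atom_particle, sc_cell, model)
        assert len(vec) == 57
        assert vec.values["D5"] is None  # core average undefined
        assert "D5" in vec.missing

    def test_vector_is_deterministic(self, sc_cell):
        model = LennardJonesModel(params={("Fe", "Fe"): (0.4, 2.3)})
        p = crystal.carve_sphere(sc_cell, 10.0, center_policy="atom")
        v1 = compute_descriptor_vector(p, sc_cell, model).as_array()
        v2 = compute_descriptor_vector(p, sc_cell, model).as_array()
        assert np.array_equal(v1, v2, equal_nan=True)


def test_bonded_counts_respect_covalent_cutoff():
    """Fe-C within 1.2x radii sum counts; like-species pairs never count."""
    pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.6, 0, 0]])
    p = particle_from(pos, species=["Fe", "C", "Fe"], diameter=12.0)
    counts = bonded_neighbor_counts(p)  # Fe-C cutoff 1.2*(1.32+0.76)=2.496
    assert counts.tolist() == [1, 1, 0]  # 2.6 Å Fe-C pair misses the cutoff
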