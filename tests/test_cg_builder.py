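"""CG mapping, virtual sites, HENM fluctuation matching and the Hamiltonian."""

import numpy as np
import pytest

from coilgel.cg.builder import (BondTable, CGTopology, HamiltonianParams,
                                HENMConvergenceError, add_virtual_sites,
                                assemble_hamiltonian, fit_henm,
                                map_structure_to_cg,
                                model_distance_fluctuations)
from coilgel.synth import gen_gaussian_network_trajectory, make_surrogate_cc
from coilgel.units import KB


@pytest.fixture(scope="module")
def cg_pentamer(pentamer, q_seq):
    topo, coords = map_structure_to_cg(pentamer, sequence=q_seq.residues)
    return add_virtual_sites(topo), coords


class TestMapping:
    def test_pentamer_site_count_and_coordinates(self, pentamer, cg_pentamer):
        topo, coords = cg_pentamer
        assert topo.n_real == 5 * 54 == 270
        assert np.allclose(coords, pentamer.alpha_carbons())

    def test_rotation_equivariance(self, pentamer, q_seq):
        _, coords = map_structure_to_cg(pentamer)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]],
                       dtype=np.float32)
        rotated = pentamer
        rotated.atoms.coord = rotated.atoms.coord @ rot.T
        _, coords2 = map_structure_to_cg(rotated)
        assert np.allclose(coords2, coords @ rot.astype(float).T, atol=1e-4)


class TestVirtualSites:
    def test_pentamer_counts(self, cg_pentamer):
        topo, _ = cg_pentamer
        kinds = [v.kind for v in topo.virtual_sites]
        assert kinds.count("intra") == 50  # 5 adjacent pairs x 10 anchors
        assert kinds.count("inter_n") == 1
        assert kinds.count("inter_c") == 1

    def test_inter_anchor_residues(self, cg_pentamer):
        topo, _ = cg_pentamer
        for v in topo.virtual_sites:
            if v.kind == "inter_n":
                assert set(topo.residue[list(v.anchors)]) == {12}
            if v.kind == "inter_c":
                assert set(topo.residue[list(v.anchors)]) == {50}

    def test_intra_midpoint_placement(self, cg_pentamer):
        topo, coords = cg_pentamer
        ext = topo.extended_coords(coords)
        for vi, v in enumerate(topo.virtual_sites):
            if v.kind == "intra":
                mid = 0.5 * (coords[v.anchors[0]] + coords[v.anchors[1]])
                assert np.abs(ext[topo.n_real + vi] - mid).max() < 1e-12

    def test_missing_anchor_raises(self, q_seq):
        from coilgel.structure_io import assign_heptad, build_ideal_pentamer
        short = assign_heptad(q_seq.residues[:30], "a")
        model = build_ideal_pentamer(short)
        topo, _ = map_structure_to_cg(model)
        with pytest.raises(KeyError):
            add_virtual_sites(topo)  # residue 50 absent


class TestHENM:
    def _triangle(self):
        x0 = np.array([[0.0, 0, 0], [10.0, 0, 0], [5.0, 8.0, 0]])
        k_true = np.array([8.0, 4.0, 2.0])
        bonds = BondTable(i=np.array([0, 0, 1]), j=np.array([1, 2, 2]),
                          k=k_true, r0=None)
        return x0, bonds, k_true

    def test_recovers_known_spring_constants(self):
        x0, bonds, k_true = self._triangle()
        frames = gen_gaussian_network_trajectory(x0, bonds, 277.0,
                                                 n_frames=10_000, seed=9)
        fitted = fit_henm(frames, cutoff=19.0)
        by_pair = {(int(a), int(b)): kk
                   for a, b, kk in zip(fitted.i, fitted.j, fitted.k)}
        for a, b, kt in zip(bonds.i, bonds.j, k_true):
            assert by_pair[(int(a), int(b))] == pytest.approx(kt, rel=0.05)

    def test_doubling_temperature_halves_fitted_k(self):
        """Equipartition: distance fluctuations scale as T/k, so a trajectory
        generated at 2T fits springs of k/2 when analyzed at T."""
        x0, bonds, k_true = self._triangle()
        hot = gen_gaussian_network_trajectory(x0, bonds, 2 * 277.0,
                                              n_frames=10_000, seed=9)
        fitted = fit_henm(hot, cutoff=19.0, temperature=277.0)
        by_pair = {(int(a), int(b)): kk
                   for a, b, kk in zip(fitted.i, fitted.j, fitted.k)}
        for a, b, kt in zip(bonds.i, bonds.j, k_true):
            assert by_pair[(int(a), int(b))] == pytest.approx(kt / 2, rel=0.07)

    def test_cutoff_excludes_long_pairs(self):
        x0 = np.array([[0.0, 0, 0], [10.0, 0, 0], [10.0, 18.0, 0]])
        bonds = BondTable(i=np.array([0, 1]), j=np.array([1, 2]),
                          k=np.array([5.0, 5.0]), r0=None)
        frames = gen_gaussian_network_trajectory(
            x0, bonds, 277.0, 4000, 1, restrained_sites=[0, 1, 2],
            restraint_k=1.0)
        fitted = fit_henm(frames, cutoff=19.0)
        pairs = set(zip(fitted.i.tolist(), fitted.j.tolist()))
        assert (0, 2) not in pairs  # mean distance 30 > 19 cutoff

    def test_single_bond_closed_form(self):
        x0 = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        sig = model_distance_fluctuations(x0, np.array([0]), np.array([1]),
                                          np.array([3.0]), 277.0)
        assert sig[0] == pytest.approx(KB * 277.0 / 3.0, rel=1e-9)


class TestHamiltonian:
    def test_zero_configuration_energy(self):
        topo, x = make_surrogate_cc(q_patch=0.0)
        from coilgel.cg.dynamics import build_protofibril
        proto, coords = build_protofibril(topo, x, 2, 200.0)  # far apart
        params = HamiltonianParams(attraction_depth=0.0)
        ham = assemble_hamiltonian(proto, 80.0, params)
        assert ham.energy(coords) == pytest.approx(0.0, abs=1e-12)

    def test_forces_match_numerical_gradient(self, rng):
        topo, x = make_surrogate_cc(q_patch=2.0)
        from coilgel.cg.dynamics import build_protofibril
        proto, coords = build_protofibril(topo, x, 2, 55.0)
        coords = coords + rng.normal(0, 0.5, coords.shape)
        ham = assemble_hamiltonian(proto, 20.0)
        _, f = ham.energy_forces(coords)
        h = 1e-6
        for i in range(0, proto.n_real, 3):
            for d in range(3):
                xp = coords.copy()
                xp[i, d] += h
                xm = coords.copy()
                xm[i, d] -= h
                num = -(ham.energy(xp) - ham.energy(xm)) / (2 * h)
                assert f[i, d] == pytest.approx(num, rel=1e-5, abs=1e-7)

    def test_doubling_dielectric_halves_electrostatics(self):
        topo, x = make_surrogate_cc(q_patch=2.0)
        from coilgel.cg.dynamics import replicate_system
        # two CCs side by side, within electrostatic range
        proto, coords = replicate_system(topo, x, [[0, 0, 0], [0, 12.0, 0]])
        params = HamiltonianParams(attraction_depth=0.0)
        e1 = assemble_hamiltonian(proto, 10.0, params).energy_terms(coords)
        e2 = assemble_hamiltonian(proto, 20.0, params).energy_terms(coords)
        assert e1["nonbonded"] != 0.0
        assert e2["nonbonded"] == pytest.approx(e1["nonbonded"] / 2, rel=1e-12)

    def test_rigid_motion_invariance(self, rng):
        topo, x = make_surrogate_cc(q_patch=2.0)
        from coilgel.cg.dynamics import build_protofibril
        proto, coords = build_protofibril(topo, x, 3, 58.0)
        ham = assemble_hamiltonian(proto, 40.0)
        e0 = ham.energy(coords)
        th = rng.uniform(0, 2 * np.pi)
        rot = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)],
                        [0, np.sin(th), np.cos(th)]])
        e1 = ham.energy(coords @ rot.T + np.array([3.0, -7.0, 11.0]))
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_missing_bonds_rejected(self):
        topo = CGTopology(residue=np.array([1]), monomer=np.array([0]),
                          cc=np.array([0]), charge=np.zeros(1),
                          mass=np.ones(1))
        with pytest.raises(ValueError):
            assemble_hamiltonian(topo, 80.0)
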