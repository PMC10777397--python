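"""Minimization, geometry scans, fibril construction and integrators."""

import numpy as np
import pytest

from coilgel.cg.builder import (BondTable, CGTopology, HamiltonianParams,
                                assemble_hamiltonian)
from coilgel.cg.dynamics import (DESK_PRESET, SimParams, build_fibril,
                                 build_protofibril, minimize, run_nve,
                                 run_nvt, scan_lattice_geometry,
                                 scan_stack_spacing)
from coilgel.synth import SURROGATE_PARAMS, make_surrogate_cc
from coilgel.units import KB, TIME_UNIT_FS


def harmonic_dimer(k=50.0, r0=10.0, mass=100.0):
    topo = CGTopology(residue=np.array([1, 1]), monomer=np.array([0, 0]),
                      cc=np.array([0, 1]), charge=np.zeros(2),
                      mass=np.full(2, mass),
                      bonds=BondTable(i=np.array([0]), j=np.array([1]),
                                      k=np.array([k]), r0=np.array([r0])))
    params = HamiltonianParams(sigma=1e-3, eps_rep=0.0, attraction_depth=0.0)
    return assemble_hamiltonian(topo, 80.0, params)


class TestMinimize:
    def test_stretched_bond_relaxes_to_rest_length(self):
        ham = harmonic_dimer()
        x0 = np.array([[0.0, 0, 0], [11.0, 0, 0]])
        res = minimize(ham, x0)
        assert res.converged
        d = np.linalg.norm(res.coords[1] - res.coords[0])
        assert d == pytest.approx(10.0, abs=1e-6)
        assert res.energy == pytest.approx(0.0, abs=1e-10)

    def test_already_minimal_converges_immediately(self):
        ham = harmonic_dimer()
        x0 = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        res = minimize(ham, x0)
        assert res.converged and res.n_iter <= 1

    def test_wca_overlap_separates_to_potential_minimum(self):
        topo = CGTopology(residue=np.array([1, 1]), monomer=np.array([0, 0]),
                          cc=np.array([0, 1]), charge=np.zeros(2),
                          mass=np.full(2, 100.0),
                          bonds=BondTable(i=np.array([], dtype=int),
                                          j=np.array([], dtype=int),
                                          k=np.array([]), r0=np.array([])))
        params = HamiltonianParams(sigma=4.0, eps_rep=2.0,
                                   attraction_depth=0.0)
        ham = assemble_hamiltonian(topo, 80.0, params)
        res = minimize(ham, np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        d = np.linalg.norm(res.coords[1] - res.coords[0])
        assert d >= 4.0 * 2 ** (1 / 6) - 1e-3


class TestScans:
    def test_constructed_minimum_recovered(self):
        res = scan_stack_spacing(energy_fn=lambda s: (s - 62.0) ** 2,
                                 s_range=(56.0, 75.0), step=1.0)
        assert res.optimum[0] == pytest.approx(62.0, abs=1.0)

    def test_repulsive_only_pushes_to_upper_bound(self):
        res = scan_stack_spacing(energy_fn=lambda s: 1.0 / s)
        assert res.optimum[0] == 75.0

    def test_separable_lattice_surface(self):
        res = scan_lattice_geometry(
            energy_fn=lambda a, d: (a - 30.0) ** 2 + (d - 28.0) ** 2)
        assert res.optimum == (30.0, 28.0)

    def test_stagger_tie_breaks_to_smaller(self):
        # symmetric in d about 30: both 28 and 32 minimal on the grid
        res = scan_lattice_geometry(
            energy_fn=lambda a, d: (a - 24.0) ** 2 + (abs(d - 30.0) - 2) ** 2)
        assert res.optimum[1] == 28.0

    def test_surrogate_protofibril_spacing_in_range(self):
        """The surrogate CC's end-to-end well sits at 60 Å, inside the
        56-75 Å scan window."""
        topo, x = make_surrogate_cc()
        res = scan_stack_spacing(topology=topo, coords=x, dielectric=40.0,
                                 params=SURROGATE_PARAMS, length=5)
        assert 58.0 <= res.optimum[0] <= 62.0
        assert res.energies.min() < -100.0


class TestFibrilConstruction:
    def test_cc_count(self):
        topo, x = make_surrogate_cc()
        fib = build_fibril(topo, x, 4, 60.0, 20.0, 30.0, length=14)
        assert fib.n_cc == 4 ** 2 * 14 == 224
        assert int(fib.topology.cc.max()) + 1 == 224

    def test_zero_stagger_is_coplanar(self):
        topo, x = make_surrogate_cc()
        fib = build_fibril(topo, x, 2, 60.0, 25.0, 0.0, length=3)
        xs = fib.coordinates[:, 0]
        assert set(np.round(xs, 6)) == set(np.round(xs[:15], 6))

    def test_lattice_spacing_by_construction(self):
        topo, x = make_surrogate_cc()
        fib = build_fibril(topo, x, 3, 60.0, 22.0, 30.0, length=2)
        ys = np.unique(np.round(fib.coordinates[:, 1], 6))
        assert np.allclose(np.diff(ys), 22.0)

    def test_overlap_rejected(self):
        topo, x = make_surrogate_cc()
        with pytest.raises(ValueError, match="overlap"):
            build_fibril(topo, x, 2, 60.0, 0.5, 0.0, length=2)


class TestNVE:
    def test_harmonic_period_matches_analytic(self):
        """Velocity-Verlet period of the dimer equals 2π√(μ/k) within 1%."""
        k, m = 50.0, 100.0
        ham = harmonic_dimer(k=k, mass=m)
        x0 = np.array([[0.0, 0, 0], [10.8, 0, 0]])
        traj = run_nve(ham, x0, timestep_fs=2.0, steps=4000, sample_every=1)
        d = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        # period from zero crossings of (d - r0)
        signs = np.sign(d - 10.0)
        crossings = np.nonzero(np.diff(signs))[0]
        period_fs = 2 * np.mean(np.diff(traj.times_fs[crossings]))
        mu = m / 2
        expected = 2 * np.pi * np.sqrt(mu / k) * TIME_UNIT_FS
        assert period_fs == pytest.approx(expected, rel=0.01)

    def test_energy_drift_shrinks_with_timestep(self):
        ham = harmonic_dimer()
        x0 = np.array([[0.0, 0, 0], [11.0, 0, 0]])
        drifts = []
        for dt in (4.0, 2.0):
            traj = run_nve(ham, x0, timestep_fs=dt, steps=2000,
                           sample_every=10)
            e = traj.total_energy
            drifts.append(abs(e[-1] - e[0]) / max(abs(e[0]), 1e-12))
        assert drifts[1] <= drifts[0] + 1e-12

    def test_momentum_conserved(self):
        ham = harmonic_dimer()
        x0 = np.array([[0.0, 0, 0], [11.0, 0, 0]])
        v0 = np.array([[0.01, 0.002, 0], [-0.003, 0.004, 0.005]])
        traj = run_nve(ham, x0, v0=v0, timestep_fs=2.0, steps=1000,
                       sample_every=1000)
        p0 = (ham.topology.mass[:, None] * v0).sum(axis=0)
        p1 = (ham.topology.mass[:, None] * traj.final_velocities).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-10 * max(np.abs(p0).max(), 1.0)


class TestNVT:
    def test_same_seed_bit_identical(self):
        ham = harmonic_dimer()
        x0 = np.array([[0.0, 0, 0], [10.5, 0, 0]])
        p = SimParams(equilibration_steps=100, production_steps=200,
                      sampling_interval=20, seed=42)
        t1 = run_nvt(ham, x0, p)
        t2 = run_nvt(ham, x0, p)
        assert np.array_equal(t1.frames, t2.frames)
        assert np.array_equal(t1.final_velocities, t2.final_velocities)

    def test_harmonic_fixture_temperature(self):
        """Mean kinetic temperature of a thermostatted dimer is the target
        within 3σ of the sampling estimate."""
        ham = harmonic_dimer()
        x0 = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        p = SimParams(temperature=277.0, timestep_fs=5.0, damping_ps=0.5,
                      equilibration_steps=2000, production_steps=20_000,
                      sampling_interval=20, seed=7)
        traj = run_nvt(ham, x0, p)
        temps = traj.temperature
        n_eff = len(temps) / 10  # conservative autocorrelation allowance
        sem = temps.std() / np.sqrt(n_eff)
        assert abs(temps.mean() - 277.0) < 3 * sem + 1.0

    def test_zero_temperature_limit_relaxes(self):
        ham = harmonic_dimer()
        x0 = np.array([[0.0, 0, 0], [11.5, 0, 0]])
        p = SimParams(temperature=1e-8, timestep_fs=5.0, damping_ps=0.1,
                      equilibration_steps=0, production_steps=4000,
                      sampling_interval=100, seed=3)
        traj = run_nvt(ham, x0, p)
        assert traj.potential[-1] < 1e-4
        d = np.linalg.norm(traj.final_positions[1] - traj.final_positions[0])
        assert d == pytest.approx(10.0, abs=0.01)
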