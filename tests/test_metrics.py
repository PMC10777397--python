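"""Radial densities, principal-axis alignment, diameters, phase diagram."""

import numpy as np
import pytest

from coilgel.metrics import (DiameterEstimate, align_principal_axes,
                             build_phase_diagram, cc_centers_of_mass,
                             com_radial_density, fibril_diameter,
                             pair_distance_distribution, radial_density)
from coilgel.synth import gen_lattice_coms


class TestRadialDensity:
    def test_single_cc_all_pairs_excluded(self, rng):
        coords = rng.normal(size=(1, 20, 3))
        prof = radial_density(coords, np.zeros(20), fibril_size=1)
        assert np.all(prof.values == 0.0)

    def test_two_sites_single_bin(self):
        coords = np.array([[[0.0, 0, 0], [10.2, 0, 0]]])
        prof = radial_density(coords, np.array([0, 1]), dr=0.5)
        centers = prof.bin_centers
        hit = np.nonzero(prof.values)[0]
        assert len(hit) == 1
        lo = prof.bin_edges[hit[0]]
        assert lo == pytest.approx(10.0)
        assert prof.values[hit[0]] == pytest.approx(1.0)

    def test_matches_bruteforce_histogram(self, rng):
        n = 60
        coords = rng.uniform(0, 30, size=(3, n, 3))
        labels = rng.integers(0, 6, size=n)
        prof = radial_density(coords, labels, dr=0.5, fibril_size=2)
        # O(n^2) loop oracle
        edges = prof.bin_edges
        counts = np.zeros(len(edges) - 1)
        for f in coords:
            for i in range(n):
                for j in range(i + 1, n):
                    if labels[i] == labels[j]:
                        continue
                    d = np.linalg.norm(f[i] - f[j])
                    b = np.searchsorted(edges, d, side="right") - 1
                    if 0 <= b < len(counts):
                        counts[b] += 1
        assert np.allclose(prof.values, counts / 3 / 2)

    def test_unlabeled_site_rejected(self):
        with pytest.raises(ValueError):
            radial_density(np.zeros((1, 3, 3)), np.array([0, 1]))


class TestCOMDensity:
    def test_two_cc_scaled_peak(self):
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0],
                            [30.0, 0, 0], [32.0, 0, 0]]])
        labels = np.array([0, 0, 1, 1])
        prof = com_radial_density(coords, labels, dr=0.5)
        hit = np.nonzero(prof.values)[0]
        assert len(hit) == 1
        assert prof.bin_edges[hit[0]] == pytest.approx(30.0)  # COMs 1 and 31
        assert prof.values[hit[0]] == pytest.approx(20_000.0)

    def test_protofibril_first_peak_at_spacing(self):
        frames, _ = gen_lattice_coms(1, 5, spacing=60.0)
        prof = com_radial_density(frames, np.arange(5), dr=0.5)
        first = np.nonzero(prof.values)[0][0]
        assert prof.bin_edges[first] == pytest.approx(60.0)

    def test_scale_factor_against_unscaled(self, rng):
        coords = rng.normal(scale=20, size=(2, 8, 3))
        labels = np.repeat(np.arange(4), 2)
        a = com_radial_density(coords, labels, scale=20_000.0)
        b = com_radial_density(coords, labels, scale=1.0)
        assert np.allclose(a.values, 20_000.0 * b.values)


class TestAlignment:
    def test_axis_aligned_input_unchanged_up_to_sign(self):
        pts = np.array([[x, 0.1 * ((x * 7) % 3 - 1), 0.5 * ((x * 5) % 5 - 2)]
                        for x in range(-5, 6)], dtype=float)
        out = align_principal_axes(pts)
        centered = pts - pts.mean(axis=0)
        assert np.allclose(np.abs(out[:, 0]), np.abs(centered[:, 0]),
                           atol=0.2)

    def test_rotation_equivariance(self, rng):
        frames, _ = gen_lattice_coms(4, 14, 20.0, stagger=10.0, jitter=0.3,
                                     seed=5)
        base = align_principal_axes(frames[0])
        th = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        again = align_principal_axes(frames[0] @ rot.T)
        assert np.allclose(np.abs(again), np.abs(base), atol=1e-6)

    def test_long_axis_lands_on_x(self):
        frames, _ = gen_lattice_coms(4, 14, 20.0, jitter=0.5, seed=2)
        out = align_principal_axes(frames[0])
        var = out.var(axis=0)
        assert var[0] == var.max()
        assert var[2] >= var[1]  # second principal axis on z

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            align_principal_axes(pts)


class TestFibrilDiameter:
    def test_constructed_lattice_diameter(self):
        """4 × 4 lattice with 2 nm spacing: lateral extent 3 bins of 2 nm,
        d̃ = diameter / 16 within one bin."""
        frames, _ = gen_lattice_coms(4, 14, 20.0, stagger=10.0, jitter=0.2,
                                     n_frames=10, seed=0)
        # shrink z slightly so the two lateral principal axes are not
        # degenerate (a perfectly square lattice has no preferred axes)
        frames[:, :, 2] *= 0.9
        est = fibril_diameter(frames, np.arange(frames.shape[1]), n_side=4)
        assert est.associated
        assert est.diameter == pytest.approx(6.0, abs=1.2)
        assert est.normalized == pytest.approx(est.diameter / 16)

    def test_dissociated_when_below_threshold(self, rng):
        # CC COMs scattered over a huge volume: no bin above threshold
        frames = rng.uniform(-300, 300, size=(4, 20, 3))
        est = fibril_diameter(frames, np.arange(20), n_side=2)
        assert not est.associated
        assert est.normalized == 0.0

    def test_normalization_is_per_total_protofibrils(self):
        frames, _ = gen_lattice_coms(4, 14, 20.0, stagger=10.0, jitter=0.2,
                                     n_frames=5, seed=1)
        est = fibril_diameter(frames, np.arange(frames.shape[1]), n_side=4)
        assert est.normalized == pytest.approx(est.diameter / 16)


class TestPhaseDiagram:
    def _est(self, d):
        associated = d > 0
        return DiameterEstimate(d, d, d if associated else 0.0,
                                d / 4 if associated else 0.0, associated)

    def test_means_match_bruteforce(self):
        runs = [(10.0, 2, [self._est(2.0), self._est(3.0)]),
                (80.0, 2, [self._est(0.0), self._est(0.0)])]
        diagram = build_phase_diagram(runs)
        cell = diagram.cell(10.0, 2)
        vals = np.array([2.0 / 4, 3.0 / 4])
        assert cell["mean"] == pytest.approx(vals.mean())
        assert cell["sd"] == pytest.approx(vals.std())
        assert cell["associated"]

    def test_all_dissociated_cell(self):
        diagram = build_phase_diagram([(80.0, 4, [self._est(0.0)] * 3)])
        cell = diagram.cell(80.0, 4)
        assert cell["mean"] == 0.0 and not cell["associated"]

    def test_single_replica_flagged(self):
        diagram = build_phase_diagram([(40.0, 2, [self._est(2.0)])])
        cell = diagram.cell(40.0, 2)
        assert cell["single_replica"] and cell["sd"] == 0.0

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            build_phase_diagram([(40.0, 2, [])])


class TestPairDistanceDistribution:
    def test_two_points_single_peak(self):
        prof = pair_distance_distribution(
            np.array([[0.0, 0, 0], [25.0, 0, 0]]), bin_width=1.0)
        assert len(prof.peaks) == 1
        assert prof.peaks[0] == pytest.approx(25.5, abs=1.0)

    def test_protofibril_peaks_at_multiples_of_spacing(self):
        frames, _ = gen_lattice_coms(1, 5, spacing=60.0)
        prof = pair_distance_distribution(frames[0], bin_width=2.0)
        for k, peak in enumerate(sorted(prof.peaks)):
            assert peak == pytest.approx(60.0 * (k + 1), abs=2.0)

    def test_normalized(self, rng):
        prof = pair_distance_distribution(rng.normal(size=(40, 3)),
                                          bin_width=0.5)
        assert np.sum(prof.p) * 0.5 == pytest.approx(1.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            pair_distance_distribution(np.zeros((1, 3)))
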