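import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from hotspot_hremd import (
    BOLTZMANN,
    Conformation,
    Trajectory,
    classify_folded,
    cluster_conformations,
    energy_histograms,
    free_energy_landscape,
    radius_of_gyration,
    rmsd,
)
from hotspot_hremd.analysis import count_threshold_crossings


def _random_coords(n, seed):
    return np.random.default_rng(seed).uniform(-1, 1, (n, 3))


class TestRMSD:
    def test_identical_conformations(self):
        x = _random_coords(6, 0)
        # sqrt of a catastrophically cancelled msd: ~1e-8 noise floor
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self):
        x = _random_coords(8, 1)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = x @ rot.T + np.array([1.0, -2.0, 0.5])
        assert rmsd(moved, x) == pytest.approx(0.0, abs=1e-9)

    @given(seed=st.integers(0, 500), angle_seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_random_rotation_invariance_property(self, seed, angle_seed):
        x = _random_coords(7, seed)
        y = _random_coords(7, seed + 1000)
        base = rmsd(x, y)
        rot = Rotation.random(rng=np.random.default_rng(angle_seed)).as_matrix()
        assert rmsd(x @ rot.T + 0.7, y) == pytest.approx(base, abs=1e-9)
        assert rmsd(x, y @ rot.T - 1.2) == pytest.approx(base, abs=1e-9)

    def test_grid_search_oracle_four_points(self):
        # independent oracle: exhaustive search over a fine Euler-angle grid
        x = np.array(
            [[0.0, 0.0, 0.0], [0.5, 0.0, 0.0], [0.0, 0.45, 0.0], [0.1, 0.1, 0.4]]
        )
        rng = np.random.default_rng(5)
        y = x + rng.normal(0, 0.08, x.shape)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        grid = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        half = np.linspace(0, np.pi, 40)
        angles = np.stack(
            np.meshgrid(grid, half, grid, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        mats = Rotation.from_euler("zyz", angles).as_matrix()
        diffs = np.einsum("kij,nj->kni", mats, xc) - yc
        best = float(np.sqrt(np.min(np.mean(np.sum(diffs**2, axis=2), axis=1))))
        assert rmsd(x, y) == pytest.approx(best, abs=1e-3)
        assert rmsd(x, y) <= best + 1e-12

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            rmsd(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_selection(self):
        x = _random_coords(6, 3)
        y = x.copy()
        y[5] += 10.0  # outlier excluded by the selection
        assert rmsd(x, y, selection=[0, 1, 2, 3, 4]) == pytest.approx(0.0, abs=1e-6)
        assert rmsd(x, y) > 1.0


class TestClassifyFolded:
    def test_below_threshold_folded(self):
        assert classify_folded(0.15) is True

    def test_exactly_at_threshold_unfolded(self):
        assert classify_folded(0.2) is False

    def test_unfolded_excursion(self):
        assert classify_folded(0.7) is False

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_folded(-0.1)


class TestRadiusOfGyration:
    def test_single_particle(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_unit_masses(self):
        d = 0.8
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        assert radius_of_gyration(coords) == pytest.approx(d / 2)

    def test_uniform_ring(self):
        r = 1.3
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        coords = np.stack([r * np.cos(theta), r * np.sin(theta), np.zeros(100)], axis=1)
        assert radius_of_gyration(coords) == pytest.approx(r, rel=1e-12)

    def test_mass_weighting(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        masses = np.array([3.0, 1.0])
        # com at 0.25; rg = sqrt((3*0.0625 + 1*0.5625)/4)
        assert radius_of_gyration(coords, masses) == pytest.approx(
            math.sqrt((3 * 0.0625 + 0.5625) / 4)
        )

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            radius_of_gyration(np.zeros((2, 3)), np.zeros(2))


class TestFEL:
    def _traj(self, frames):
        return Trajectory([Conformation(f) for f in frames])

    def test_all_frames_identical_single_bin(self):
        x = _random_coords(5, 7)
        fel = free_energy_landscape(self._traj([x] * 10), x, 300.0, bins=8)
        occupied = np.isfinite(fel.free_energy)
        assert occupied.sum() == 1
        assert fel.free_energy[occupied][0] == 0.0

    def test_equal_populations_zero_gap(self):
        x = _random_coords(5, 8)
        y = x * 2.0
        fel = free_energy_landscape(self._traj([x, y] * 5), x, 300.0, bins=4)
        vals = fel.free_energy[np.isfinite(fel.free_energy)]
        assert vals == pytest.approx([0.0, 0.0])

    def test_boltzmann_inversion_75_25(self):
        temperature = 2.5 / BOLTZMANN  # kT = 2.5 kJ/mol
        x = _random_coords(5, 9)
        y = x * 2.0
        frames = [x] * 75 + [y] * 25
        fel = free_energy_landscape(self._traj(frames), x, temperature, bins=4)
        vals = np.sort(fel.free_energy[np.isfinite(fel.free_energy)])
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(2.5 * math.log(3.0), rel=1e-9)

    def test_duplicating_frames_invariant(self):
        frames = [_random_coords(5, s) for s in range(6)]
        ref = frames[0]
        a = free_energy_landscape(self._traj(frames), ref, 300.0, bins=5)
        b = free_energy_landscape(self._traj(frames * 2), ref, 300.0, bins=5)
        np.testing.assert_allclose(a.free_energy, b.free_energy, equal_nan=True)


class TestClustering:
    def _traj(self, frames):
        return Trajectory([Conformation(f) for f in frames])

    def test_all_identical_one_cluster(self):
        x = _random_coords(5, 11)
        cs = cluster_conformations(self._traj([x] * 7), cutoff=0.05)
        assert cs.n_clusters == 1
        assert cs.populations == (7,)
        assert all(a == 0 for a in cs.assignments)

    def test_two_bundles(self):
        rng = np.random.default_rng(12)
        base_a = _random_coords(6, 13)
        base_b = base_a + np.array([5.0, 0.0, 0.0])  # rmsd-distant shape change
        base_b[0] += 3.0
        bundle_a = [base_a + rng.normal(0, 0.005, base_a.shape) for _ in range(4)]
        bundle_b = [base_b + rng.normal(0, 0.005, base_b.shape) for _ in range(3)]
        cs = cluster_conformations(self._traj(bundle_a + bundle_b), cutoff=0.1)
        assert cs.n_clusters == 2
        assert sorted(cs.populations, reverse=True) == [4, 3]

    def test_tiny_cutoff_singletons(self):
        frames = [_random_coords(5, s) for s in range(5)]
        cs = cluster_conformations(self._traj(frames), cutoff=1e-9)
        assert cs.n_clusters == 5

    def test_representative_is_member(self):
        frames = [_random_coords(5, s) for s in range(8)]
        cs = cluster_conformations(self._traj(frames), cutoff=0.5)
        for cid, rep in enumerate(cs.representatives):
            assert cs.assignments[rep] == cid

    def test_deterministic_tie_break(self):
        x = _random_coords(5, 20)
        y = x + 100.0 * np.eye(5, 3)  # distinct shape
        cs = cluster_conformations(self._traj([x, x, y, y]), cutoff=0.01)
        # both clusters have 2 neighbours; frame 0 must win the tie
        assert cs.representatives[0] == 0

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            cluster_conformations(self._traj([_random_coords(5, 0)]), cutoff=0.0)


class TestEnergyHistograms:
    def test_identical_distributions_full_overlap(self):
        rng = np.random.default_rng(3)
        e = rng.normal(0, 1, 4000)
        hists = energy_histograms([e, e.copy()], n_bins=40)
        assert hists.overlaps[(0, 1)] == pytest.approx(1.0)

    def test_disjoint_supports_zero_overlap(self):
        a = np.linspace(0, 1, 100)
        b = np.linspace(10, 11, 100)
        hists = energy_histograms([a, b], n_bins=50)
        assert hists.overlaps[(0, 1)] == pytest.approx(0.0)

    def test_gaussians_two_sigma_apart_closed_form(self):
        # overlap coefficient of N(0,1) and N(2,1) is 2*Phi(-1)
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 200_000)
        b = rng.normal(2, 1, 200_000)
        hists = energy_histograms([a, b], n_bins=120)
        expected = 2 * norm.cdf(-1.0)
        assert hists.overlaps[(0, 1)] == pytest.approx(expected, abs=0.02)

    def test_empty_rung_flagged_not_zero(self):
        a = np.linspace(0, 1, 50)
        hists = energy_histograms([a, np.array([]), a], n_bins=10)
        assert hists.excluded == (1,)
        assert (0, 1) not in hists.overlaps
        assert (1, 2) not in hists.overlaps

    def test_single_rung_rejected(self):
        with pytest.raises(ValueError, match="two rungs"):
            energy_histograms([np.zeros(5)])


class TestCrossingCounts:
    def test_counts_both_directions(self):
        values = np.array([0.1, 0.3, 0.1, 0.25, 0.15])
        up, down = count_threshold_crossings(values, 0.2)
        assert (up, down) == (2, 2)

    def test_no_crossings(self):
        assert count_threshold_crossings(np.full(10, 0.05), 0.2) == (0, 0)
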