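import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from hotspot_hremd import (
    BOLTZMANN,
    COULOMB,
    Bond,
    Conformation,
    Particle,
    ToySystem,
    double_well_dimer,
    generate_fixture,
    pair_energy,
    sample,
    total_energy,
)
from hotspot_hremd.toy_system import dimer_radial_potential


class TestPairEnergy:
    def test_lj_terms_cancel_at_unit_values(self):
        a = Particle(0, 1, 0.0, 1.0, 1.0)
        b = Particle(1, 2, 0.0, 1.0, 1.0)
        assert pair_energy(a, b, 1.0) == pytest.approx(0.0)

    def test_all_zero_parameters(self):
        a = Particle(0, 1, 0.0, 0.0, 0.0)
        b = Particle(1, 2, 0.0, 0.0, 0.0)
        for r in (0.1, 1.0, 7.3):
            assert pair_energy(a, b, r) == 0.0

    def test_coulomb_constant(self):
        # unit charges at 1 nm: energy equals the Coulomb prefactor itself,
        # e^2/(4 pi eps0) in kJ/mol nm = 138.935458
        a = Particle(0, 1, 1.0, 0.0, 0.0)
        b = Particle(1, 2, 1.0, 0.0, 0.0)
        assert pair_energy(a, b, 1.0) == pytest.approx(138.935458, rel=1e-9)
        assert pair_energy(a, b, 0.5) == pytest.approx(2 * COULOMB, rel=1e-12)

    def test_nonpositive_distance_rejected(self):
        a = Particle(0, 1, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            pair_energy(a, a, 0.0)
        with pytest.raises(ValueError):
            pair_energy(a, a, -1.0)

    @given(
        qa=st.floats(-1, 1), qb=st.floats(-1, 1),
        c6a=st.floats(0, 1), c6b=st.floats(0, 1),
        c12a=st.floats(0, 1), c12b=st.floats(0, 1),
        r=st.floats(0.05, 5.0),
    )
    def test_symmetric_in_particles(self, qa, qb, c6a, c6b, c12a, c12b, r):
        a = Particle(0, 1, qa, c6a, c12a)
        b = Particle(1, 2, qb, c6b, c12b)
        assert pair_energy(a, b, r) == pair_energy(b, a, r)


class TestTotalEnergy:
    def test_bond_at_equilibrium_zero(self):
        particles = [Particle(0, 1, 0.0, 0.0, 0.0), Particle(1, 2, 0.0, 0.0, 0.0)]
        system = ToySystem(
            particles=particles,
            bonds=[Bond(0, 1, 0.5, 800.0)],
            native_coords=np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]),
            temperature=300.0,
            residue_count=2,
        )
        assert total_energy(system, Conformation(system.native_coords)) == 0.0

    def test_three_particle_brute_force(self, tiny_system):
        conf = Conformation(tiny_system.native_coords)
        # independent oracle: explicit sum over the pair list
        coords = conf.coords
        expected = 0.0
        for b in tiny_system.bonds:
            r = np.linalg.norm(coords[b.i] - coords[b.j])
            expected += 0.5 * b.k * (r - b.r0) ** 2
        excluded = {(b.i, b.j) for b in tiny_system.bonds}
        for i in range(3):
            for j in range(i + 1, 3):
                if (i, j) in excluded or (j, i) in excluded:
                    continue
                r = np.linalg.norm(coords[i] - coords[j])
                expected += pair_energy(
                    tiny_system.particles[i], tiny_system.particles[j], r
                )
        assert total_energy(tiny_system, conf) == pytest.approx(expected, rel=1e-12)

    def test_zero_nonbonded_leaves_bonded_only(self, tiny_system):
        params = tiny_system.native_params
        params.charge[:] = 0.0
        params.sqrt_c6[:] = 0.0
        params.sqrt_c12[:] = 0.0
        coords = tiny_system.native_coords
        bonded = sum(
            0.5 * b.k * (np.linalg.norm(coords[b.i] - coords[b.j]) - b.r0) ** 2
            for b in tiny_system.bonds
        )
        assert total_energy(
            tiny_system, Conformation(coords), params
        ) == pytest.approx(bonded, rel=1e-12)

    def test_size_mismatch_rejected(self, tiny_system):
        with pytest.raises(ValueError, match="particles"):
            total_energy(tiny_system, Conformation(np.zeros((5, 3))))

    def test_brute_force_oracle_random_systems(self):
        # full pair-list enumeration on random systems up to 10 particles
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(3, 11))
            particles = [
                Particle(
                    i,
                    i + 1,
                    float(rng.normal(0, 0.2)),
                    float(rng.uniform(0, 0.05)),
                    float(rng.uniform(0, 0.005)),
                )
                for i in range(n)
            ]
            bonds = [Bond(i, i + 1, 0.4, 500.0) for i in range(n - 1)]
            coords = rng.uniform(0, 2, (n, 3))
            system = ToySystem(
                particles=particles,
                bonds=bonds,
                native_coords=coords,
                temperature=300.0,
                residue_count=n,
            )
            expected = sum(
                0.5 * b.k * (np.linalg.norm(coords[b.i] - coords[b.j]) - b.r0) ** 2
                for b in bonds
            )
            excluded = {(b.i, b.j) for b in bonds} | {(b.j, b.i) for b in bonds}
            for i in range(n):
                for j in range(i + 1, n):
                    if (i, j) not in excluded:
                        expected += pair_energy(
                            particles[i],
                            particles[j],
                            float(np.linalg.norm(coords[i] - coords[j])),
                        )
            got = total_energy(system, Conformation(coords))
            assert got == pytest.approx(expected, rel=1e-10)


class TestSampler:
    def test_frozen_sampler_keeps_initial_conformation(self, tiny_system):
        traj = sample(tiny_system, n_steps=50, seed=0, step_size=0.0, frame_interval=10)
        for fr in traj.frames:
            np.testing.assert_array_equal(fr.coords, tiny_system.native_coords)

    def test_same_seed_identical_trajectories(self, tiny_system):
        t1 = sample(tiny_system, n_steps=200, seed=7, frame_interval=20)
        t2 = sample(tiny_system, n_steps=200, seed=7, frame_interval=20)
        np.testing.assert_array_equal(t1.coordinates(), t2.coordinates())

    def test_different_seed_differs(self, tiny_system):
        t1 = sample(tiny_system, n_steps=200, seed=7, frame_interval=20)
        t2 = sample(tiny_system, n_steps=200, seed=8, frame_interval=20)
        assert not np.array_equal(t1.coordinates(), t2.coordinates())

    def test_invalid_temperature_rejected(self, tiny_system):
        with pytest.raises(ValueError, match="temperature"):
            sample(tiny_system, n_steps=10, seed=0, temperature=-5.0)

    def test_bond_length_variance_matches_equipartition(self):
        # stiff harmonic dimer: Var(r) ~= kT/k_spring
        k_spring = 8000.0
        particles = [Particle(0, 1, 0.0, 0.0, 0.0), Particle(1, 2, 0.0, 0.0, 0.0)]
        system = ToySystem(
            particles=particles,
            bonds=[Bond(0, 1, 0.5, k_spring)],
            native_coords=np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]),
            temperature=300.0,
            residue_count=2,
        )
        traj = sample(system, n_steps=200_000, seed=3, step_size=0.02, frame_interval=20)
        r = np.array(
            [np.linalg.norm(fr.coords[1] - fr.coords[0]) for fr in traj.frames]
        )
        r = r[len(r) // 5 :]
        expected = BOLTZMANN * 300.0 / k_spring
        # 3-sigma band via the chi^2-ish standard error of a variance estimate
        n_eff = len(r) / 10  # conservative correlation allowance
        se = expected * math.sqrt(2.0 / n_eff)
        assert abs(np.var(r) - expected) < 3 * se

    def test_two_state_populations_match_partition_function(self):
        # double-well dimer: short-well occupancy vs 1-D quadrature oracle
        system = double_well_dimer(temperature=400.0)
        potential = dimer_radial_potential(system)
        beta = 1.0 / (BOLTZMANN * 400.0)
        r_barrier = 0.4157  # location of the potential maximum
        norm = quad(
            lambda r: r * r * np.exp(-beta * potential(r)), 0.12, 3.0, limit=300
        )[0]
        p_short_exact = (
            quad(
                lambda r: r * r * np.exp(-beta * potential(r)), 0.12, r_barrier,
                limit=300,
            )[0]
            / norm
        )
        traj = sample(system, n_steps=400_000, seed=11, step_size=0.06, frame_interval=40)
        r = np.array(
            [np.linalg.norm(fr.coords[1] - fr.coords[0]) for fr in traj.frames]
        )
        r = r[len(r) // 4 :]
        p_short = float(np.mean(r < r_barrier))
        n_eff = len(r) / 50  # barrier crossings are slow; be conservative
        se = math.sqrt(p_short_exact * (1 - p_short_exact) / n_eff)
        assert abs(p_short - p_short_exact) < 3 * se


class TestGenerateFixture:
    def test_same_seed_identical(self):
        a = generate_fixture(8, (2, 6), 5.0, seed=9)
        b = generate_fixture(8, (2, 6), 5.0, seed=9)
        assert a.particles == b.particles
        np.testing.assert_array_equal(a.native_coords, b.native_coords)

    def test_duplicate_hotspots_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            generate_fixture(8, (2, 2), 5.0, seed=0)

    def test_out_of_range_hotspots_rejected(self):
        with pytest.raises(ValueError, match="within"):
            generate_fixture(8, (2, 9), 5.0, seed=0)

    def test_strength_below_one_rejected(self):
        with pytest.raises(ValueError, match="strength"):
            generate_fixture(8, (2, 6), 0.5, seed=0)

    def test_strength_one_matches_background_scale(self):
        system = generate_fixture(12, (3, 8), 1.0, seed=5)
        params = system.native_params
        hot = np.isin(system.residue_ids, (3, 8))
        # at strength 1 hot-spot parameters fall inside the background spread
        assert params.sqrt_c6[hot].max() <= params.sqrt_c6[~hot].max() * 1.2
        assert np.abs(params.charge[hot]).max() == pytest.approx(
            np.abs(params.charge[~hot]).max(), rel=1e-9
        )

    def test_hotspots_strengthened(self):
        system = generate_fixture(12, (3, 8), 6.0, seed=5)
        params = system.native_params
        hot = np.isin(system.residue_ids, (3, 8))
        assert params.sqrt_c6[hot].min() > 3 * params.sqrt_c6[~hot].max()

    def test_native_coords_compact(self):
        system = generate_fixture(12, (3, 8), 5.0, seed=5)
        from hotspot_hremd.analysis import radius_of_gyration

        extended = 0.38 * 12 / 2
        assert radius_of_gyration(system.native_coords) < 0.5 * extended


class TestInvariantValidation:
    def test_negative_sqrt_c6_rejected(self):
        with pytest.raises(ValueError):
            Particle(0, 1, 0.0, -0.1, 0.0)

    def test_zero_residue_id_rejected(self):
        with pytest.raises(ValueError):
            Particle(0, 0, 0.0, 0.0, 0.0)

    def test_self_bond_rejected(self):
        with pytest.raises(ValueError):
            Bond(2, 2, 0.4, 100.0)

    def test_missing_residue_id_rejected(self):
        particles = [Particle(0, 1, 0.0, 0.0, 0.0), Particle(1, 3, 0.0, 0.0, 0.0)]
        with pytest.raises(ValueError, match="residue"):
            ToySystem(
                particles=particles,
                bonds=[],
                native_coords=np.zeros((2, 3)),
                temperature=300.0,
                residue_count=3,
            )
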