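"""Tests for the bead-spring energetics, dynamics, and stress machinery."""
import copy

import numpy as np
import pytest

from pgmech import (PatchConfig, generate_patch, ForceFieldParams,
                    StrainSpec, apply_strain, measure_stress,
                    pressure_profile, relax_patch)
from pgmech import units
from pgmech.mechanics_engine import (Topology, Trajectory, compute_forces,
                                     langevin_run, strain_sweep_specs,
                                     virial_stress_components)


@pytest.fixture(scope="module")
def straight_patch():
    """A jitter-free, perfectly laid-out patch: every term at its minimum."""
    cfg = PatchConfig(mean_length=4, sd_length=0, n_strands=2, spacing=3.0,
                      spacing_jitter=0.0, randomize_offsets=False,
                      inter_peptide_angle=90.0, seed=0)
    return generate_patch(cfg)


class TestEnergyAndForces:
    def test_ideal_lattice_has_zero_energy(self, straight_patch):
        params = ForceFieldParams()
        topo = Topology(straight_patch, params)
        e, f, _ = compute_forces(topo, topo.positions(), straight_patch.box)
        assert e == pytest.approx(0.0, abs=1e-9)
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-9)

    def test_single_stretched_bond_is_harmonic(self, straight_patch):
        params = ForceFieldParams()
        topo = Topology(straight_patch, params)
        pos = topo.positions().copy()
        # displace the first bead (GlcNAc, no stem) along -x: stays
        # collinear, so only its bond stretches
        i = straight_patch.strands[0].start
        delta = 0.05
        pos[i, 0] -= delta
        e, f, _ = compute_forces(topo, pos, straight_patch.box)
        assert e == pytest.approx(0.5 * params.k_bond * delta**2, rel=1e-9)
        assert np.linalg.norm(f[i]) == pytest.approx(params.k_bond * delta,
                                                     rel=1e-9)

    def test_forces_match_numerical_gradient(self, small_linked_patch,
                                             ff_params):
        topo = Topology(small_linked_patch, ff_params)
        topo.pair_refresh_interval = 1  # exact pair list for differencing
        rng = np.random.default_rng(4)
        pos = topo.positions() + 0.04 * rng.normal(
            size=(topo.n_particles, 3))
        _, f, _ = compute_forces(topo, pos, small_linked_patch.box)
        h = 1e-6
        for _ in range(40):
            i = rng.integers(topo.n_particles)
            a = rng.integers(3)
            pp = pos.copy()
            pp[i, a] += h
            ep, _, _ = compute_forces(topo, pp, small_linked_patch.box)
            pm = pos.copy()
            pm[i, a] -= h
            em, _, _ = compute_forces(topo, pm, small_linked_patch.box)
            f_num = -(ep - em) / (2 * h)
            assert f_num == pytest.approx(f[i, a], rel=1e-5, abs=1e-5)

    def test_overlapping_beads_give_finite_force(self, straight_patch):
        params = ForceFieldParams()
        topo = Topology(straight_patch, params)
        pos = topo.positions().copy()
        # drop a stem tip exactly onto a bead of the other strand
        pos[straight_patch.n_beads] = pos[straight_patch.strands[1].start]
        e, f, _ = compute_forces(topo, pos, straight_patch.box)
        assert np.isfinite(e) and np.all(np.isfinite(f))


class TestDynamics:
    def test_energy_conservation_without_thermostat(self, straight_patch):
        params = ForceFieldParams(gamma=0.0, dt=0.002)
        topo = Topology(straight_patch, params)
        topo.pair_refresh_interval = 1
        rng = np.random.default_rng(0)
        masses = topo.masses

        energies = []

        def cb(step, pos, vel, virial):
            e, _, _ = compute_forces(topo, pos, straight_patch.box)
            ke = 0.5 * float(np.sum(masses[:, None] * vel**2))
            energies.append(e + ke)

        langevin_run(topo, 10000, seed=0, sample_stride=100, callback=cb)
        energies = np.asarray(energies)
        n = len(energies) // 10
        drift = abs(energies[-n:].mean() - energies[:n].mean())
        assert drift / abs(energies.mean()) < 1e-4

    def test_frozen_particles_do_not_move(self, tiny_patch, ff_params):
        topo = Topology(tiny_patch, ff_params)
        frozen = np.zeros(topo.n_particles, dtype=bool)
        frozen[: tiny_patch.n_beads] = True
        frames, pos, _ = langevin_run(topo, 200, seed=1, frozen=frozen)
        assert np.allclose(frames[0][: tiny_patch.n_beads],
                           pos[: tiny_patch.n_beads])


class TestStress:
    def test_single_spring_virial_hand_value(self, straight_patch):
        # one harmonic bond under 10 pN tension spanning a 10x10x4 box:
        # sigma_xx = f*Lx/V = 0.25 MPa
        params = ForceFieldParams(ev_epsilon=1e-12, ev_sigma=1e-3)
        patch = straight_patch.copy()
        patch.box = np.array([10.0, 10.0, 4.0])
        topo = Topology(patch, params)
        # keep a single periodic bond: both endpoints at the same place so
        # the minimum-image separation is exactly Lx
        f_pn = 10.0
        f_internal = f_pn / units.kbt_pn_nm(params.temperature)
        topo.bond_i = np.array([0])
        topo.bond_j = np.array([1])
        topo.bond_k = np.array([100.0])
        r = 4.0  # separation along x; min image keeps it at 4
        topo.bond_r0 = np.array([r - f_internal / 100.0])
        topo.bond_contour = np.array([np.inf])
        topo.angles = np.empty((0, 3), dtype=int)
        topo.dihedrals = np.empty((0, 4), dtype=int)
        topo.dihedral_phi0 = np.empty(0)
        pos = np.zeros((topo.n_particles, 3))
        pos[1, 0] = r
        _, _, virial = compute_forces(topo, pos, patch.box)
        volume = 10.0 * 10.0 * 4.0
        sigma_xx_mpa = units.stress_kbt_to_mpa(-virial[0] / volume,
                                               params.temperature)
        assert sigma_xx_mpa == pytest.approx(f_pn * r / volume, rel=1e-9)

    def test_kinetic_stress_reproduces_ideal_gas(self, straight_patch):
        params = ForceFieldParams()
        topo = Topology(straight_patch, params)
        rng = np.random.default_rng(3)
        vel = rng.normal(size=(topo.n_particles, 3)) / np.sqrt(
            topo.masses[:, None])
        comps = virial_stress_components(straight_patch, params,
                                         velocities=vel, h_eff=4.0)
        volume = straight_patch.box[0] * straight_patch.box[1] * 4.0
        expected = topo.n_particles / volume
        assert np.mean(comps["kinetic"]) == pytest.approx(
            expected, rel=4 / np.sqrt(3 * topo.n_particles))

    def test_noninteracting_frozen_beads_zero_configurational_stress(
            self, straight_patch):
        params = ForceFieldParams()
        comps = virial_stress_components(straight_patch, params)
        assert np.allclose(comps["configurational"], 0.0, atol=1e-12)


class TestStrainProtocol:
    def test_zero_strain_is_identity(self, small_relaxed_patch):
        out = apply_strain(small_relaxed_patch, StrainSpec("glycan", 0.0))
        assert np.allclose(out.positions, small_relaxed_patch.positions)
        assert np.allclose(out.box, small_relaxed_patch.box)

    def test_affine_scaling_on_glycan_axis(self, small_relaxed_patch):
        out = apply_strain(small_relaxed_patch, StrainSpec("glycan", 0.1))
        assert out.box[0] == pytest.approx(1.1 * small_relaxed_patch.box[0])
        assert out.box[1] == small_relaxed_patch.box[1]
        assert np.allclose(out.positions[:, 0],
                           1.1 * small_relaxed_patch.positions[:, 0])

    def test_negative_strain_rejected(self):
        with pytest.raises(ValueError):
            StrainSpec("glycan", -0.1)

    def test_sweep_spans_reported_strain_ranges(self):
        specs = strain_sweep_specs()
        g = [s.epsilon for s in specs if s.axis == "glycan"]
        p = [s.epsilon for s in specs if s.axis == "peptide"]
        assert min(g) == pytest.approx(0.0125) and max(g) == pytest.approx(
            0.175)
        assert min(p) == pytest.approx(0.05) and max(p) == pytest.approx(0.45)

    def test_topology_conserved_by_mechanics(self, small_relaxed_patch,
                                             small_linked_patch):
        # relaxation and straining never change the particle bookkeeping
        strained = apply_strain(small_relaxed_patch,
                                StrainSpec("peptide", 0.3))
        for a, b in ((small_relaxed_patch, small_linked_patch),
                     (strained, small_linked_patch)):
            assert a.n_beads == b.n_beads
            assert a.n_stems == b.n_stems
            assert a.n_strands == b.n_strands
            assert a.n_links == b.n_links


class TestRelaxation:
    def test_fixed_point_of_relaxed_dimensions(self, small_relaxed_patch,
                                               ff_params):
        again, series = relax_patch(small_relaxed_patch, ff_params,
                                    n_steps=1500, seed=21)
        drift = np.abs(again.box[:2] / small_relaxed_patch.box[:2] - 1.0)
        assert np.all(drift < 0.02)

    def test_prestretched_network_contracts(self, small_relaxed_patch,
                                            ff_params):
        stretched = apply_strain(small_relaxed_patch,
                                 StrainSpec("glycan", 0.15))
        rec0 = measure_stress(stretched, ff_params, n_steps=400, seed=5)
        relaxed, _ = relax_patch(stretched, ff_params, n_steps=3000, seed=6)
        assert relaxed.box[0] < stretched.box[0]
        rec1 = measure_stress(relaxed, ff_params, n_steps=400, seed=7)
        assert abs(rec1.sigma_g) < max(0.5 * abs(rec0.sigma_g), 0.3)


class TestPressureProfile:
    def test_virial_consistency_with_total_stress(self, small_relaxed_patch,
                                                  ff_params):
        # z-integral of the slab profile equals the in-plane virial stress
        rec, traj = measure_stress(small_relaxed_patch, ff_params,
                                   n_steps=300, seed=9,
                                   return_trajectory=True)
        prof = pressure_profile(traj, axis=2, slab_width=0.2,
                                smooth_window=0.0)
        slab_area = traj.box[0] * traj.box[1]
        integral = float(np.sum(prof.stress) * prof.slab_width * slab_area)
        # direct: same frames, equipartition kinetic part
        total = 0.0
        topo = Topology(small_relaxed_patch, ff_params)
        for frame in traj.frames:
            _, _, virial = compute_forces(topo, frame, traj.box)
            kin = topo.n_particles
            total += -(0.5 * (virial[0] + virial[1]) + kin)
        total = units.stress_kbt_to_mpa(total / traj.n_frames,
                                        ff_params.temperature)
        assert integral == pytest.approx(total, rel=0.01)

    def test_slab_width_larger_than_box_rejected(self, small_relaxed_patch,
                                                 ff_params):
        rec, traj = measure_stress(small_relaxed_patch, ff_params,
                                   n_steps=100, seed=2,
                                   return_trajectory=True)
        with pytest.raises(ValueError):
            pressure_profile(traj, axis=0, slab_width=1e4)
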