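"""Tests for persistence length, thickness, pores, angles, and unit area."""
import numpy as np
import pytest

from pgmech import (PatchConfig, generate_patch, generate_wlc_ensemble,
                    make_gaussian_profile, persistence_length,
                    peptide_angle_series, thickness_from_density,
                    thickness_from_stress, max_pore_radius, unit_area,
                    glycan_angle_stats, structure_report, apply_strain,
                    StrainSpec, measure_stress, ForceFieldParams,
                    PressureProfile, DensityProfile)
from pgmech.mechanics_engine import Topology, Trajectory, langevin_run
from pgmech.structure_metrics import (density_profile,
                                      max_pore_radius_trajectory,
                                      unwrap_strand)

W10 = 2.0 * np.sqrt(2.0 * np.log(10.0))  # 10%-width of a unit Gaussian / sigma


class TestPersistenceLength:
    def test_straight_chains_are_not_estimable(self):
        chains = np.zeros((4, 40, 3))
        chains[:, :, 0] = np.arange(40) * 0.5
        assert persistence_length(chains) is None

    def test_recovers_generating_lp(self, wlc_reference_ensemble):
        lp = persistence_length(wlc_reference_ensemble)
        assert lp == pytest.approx(13.6, rel=0.05)

    @pytest.mark.parametrize("lp_true", [2.0, 10.0, 50.0])
    def test_parameter_recovery_across_stiffness_range(self, lp_true):
        ens = generate_wlc_ensemble(500, 320, b=0.515, lp=lp_true,
                                    seed=int(lp_true))
        assert persistence_length(ens) == pytest.approx(lp_true, rel=0.10)

    def test_too_short_chains_rejected(self):
        with pytest.raises(ValueError):
            persistence_length(np.zeros((2, 5, 3)))

    def test_simulated_glycan_strand_matches_calibration(self, ff_params):
        # a free 320-saccharide strand (no peptides, as in the calibration
        # protocol) with default bending stiffness has lp ~ 13.6 nm
        cfg = PatchConfig(mean_length=160, sd_length=0, n_strands=1,
                          spacing=30.0, spacing_jitter=0.0, seed=2,
                          box_height=30.0)
        patch = generate_patch(cfg)
        patch.stem_anchor = np.empty(0, dtype=int)
        patch.stem_phase = np.empty(0)
        patch.stem_tip = np.empty((0, 3))
        patch.stem_state = np.empty(0, dtype=int)
        # start from an equilibrium worm-like-chain conformation
        ens = generate_wlc_ensemble(1, patch.n_beads - 1, b=0.515, lp=13.6,
                                    seed=11)
        patch.positions[:] = ens.chains[0] + np.array([0.0, 15.0, 0.0])
        topo = Topology(patch, ff_params)
        frames, _, _ = langevin_run(topo, 20000, seed=4, sample_stride=200)
        confs = np.array([unwrap_strand(f[:patch.n_beads], patch.box)
                          for f in frames[25:]])
        lp = persistence_length(confs, fit_cutoff=4.0)
        assert lp == pytest.approx(13.6, rel=0.10)


class TestPeptideAngles:
    def _frozen_series(self, increments):
        phases = np.concatenate([[0.0], np.cumsum(increments)])
        cfg = PatchConfig(mean_length=len(phases), sd_length=0, n_strands=1,
                          spacing=4.0, spacing_jitter=0.0, seed=0)
        patch = generate_patch(cfg)
        patch.stem_phase[:] = phases
        rad = np.radians(phases)
        anchors = patch.positions[patch.stem_anchor]
        patch.stem_tip[:] = anchors + np.column_stack(
            [np.zeros_like(rad), np.cos(rad), np.sin(rad)])
        frame = np.vstack([patch.positions, patch.stem_tip])
        traj = Trajectory(frames=frame[None], box=patch.box, patch=patch,
                          params=ForceFieldParams())
        return peptide_angle_series(traj)

    def test_constant_ninety_degrees(self):
        series = self._frozen_series([90.0] * 5)
        assert series[0] == pytest.approx(90.0, abs=1e-6)

    def test_alternating_angles_average_to_ninety(self):
        series = self._frozen_series([80.0, 100.0] * 3)
        assert series[0] == pytest.approx(90.0, abs=1e-6)

    def test_strand_initialized_off_native_angle_relaxes_toward_it(
            self, ff_params):
        # native periodicity is four per turn; a strand built at 120 deg
        # drifts toward 90 deg
        cfg = PatchConfig(mean_length=15, sd_length=0, n_strands=1,
                          spacing=4.0, spacing_jitter=0.0,
                          inter_peptide_angle=120.0, seed=3)
        patch = generate_patch(cfg)
        topo = Topology(patch, ff_params)
        frames, _, _ = langevin_run(topo, 4000, seed=5, sample_stride=100)
        traj = Trajectory(frames=frames, box=patch.box, patch=patch,
                          params=ff_params)
        series = peptide_angle_series(traj)
        assert series[0] == pytest.approx(120.0, abs=1e-6)
        assert abs(series[-10:].mean() - 90.0) < abs(120.0 - 90.0)


class TestThicknessFromDensity:
    def test_rectangular_slab(self):
        z = np.arange(-3.0, 3.0, 0.02)
        density = np.where(np.abs(z) <= 1.5, 5.0, 0.0)
        prof = DensityProfile(z=z, density=density, bin_width=0.02)
        assert thickness_from_density(prof) == pytest.approx(3.0, abs=0.05)

    def test_gaussian_closed_form(self):
        prof = make_gaussian_profile(sigma=0.797, grid_step=0.01)
        assert thickness_from_density(prof) == pytest.approx(0.797 * W10,
                                                             abs=0.01)

    def test_triangular_profile(self):
        z = np.arange(-2.5, 2.5, 0.01)
        density = np.clip(1.0 - np.abs(z) / 2.0, 0.0, None)
        prof = DensityProfile(z=z, density=density, bin_width=0.01)
        assert thickness_from_density(prof) == pytest.approx(3.6, abs=0.02)

    def test_bounded_by_analyzed_range(self, small_relaxed_patch, ff_params):
        rec, traj = measure_stress(small_relaxed_patch, ff_params,
                                   n_steps=300, seed=3,
                                   return_trajectory=True)
        prof = density_profile(traj)
        t = thickness_from_density(prof)
        assert 0.0 <= t <= prof.z.max() - prof.z.min() + prof.bin_width


class TestThicknessFromStress:
    def test_zero_profile_not_estimable(self):
        prof = PressureProfile(centers=np.linspace(-3, 3, 61),
                               stress=np.zeros(61), slab_width=0.1)
        assert thickness_from_stress(prof) is None

    def test_baseline_plus_gaussian(self):
        z = np.linspace(-5, 5, 1001)
        stress = 1.0 + np.exp(-0.5 * (z / 0.7) ** 2)
        prof = PressureProfile(centers=z, stress=stress, slab_width=z[1] - z[0])
        assert thickness_from_stress(prof) == pytest.approx(0.7 * W10,
                                                            abs=0.03)


class TestMaxPoreRadius:
    def test_single_bead_torus_geometry(self):
        res = max_pore_radius(np.array([[0.0, 0.0]]), (10.0, 10.0),
                              bead_radius=0.0, resolution=0.1)
        assert res.radius == pytest.approx(np.sqrt(50.0), abs=0.05)

    def test_rectangular_lattice_circumradius(self):
        xs, ys = np.meshgrid(np.arange(0, 10, 2.0), np.arange(0, 10, 1.0))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        res = max_pore_radius(pts, (10.0, 10.0), bead_radius=0.25,
                              resolution=0.05)
        expected = np.hypot(2.0, 1.0) / 2.0 - 0.25
        assert res.radius == pytest.approx(expected, abs=0.02)

    def test_grid_matches_fine_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pts = rng.uniform(0, 8, size=(12, 2))
            coarse = max_pore_radius(pts, (8.0, 8.0), bead_radius=0.2,
                                     resolution=0.2, refine=False)
            fine = max_pore_radius(pts, (8.0, 8.0), bead_radius=0.2,
                                   resolution=0.02, refine=False)
            assert abs(coarse.radius - fine.radius) <= 0.2

    def test_invalid_resolution(self):
        with pytest.raises(ValueError):
            max_pore_radius(np.zeros((1, 2)), (5, 5), resolution=0)


class TestGlycanAngleStats:
    def _line_trajectory(self, patch):
        frame = np.vstack([patch.positions, patch.stem_tip])
        return Trajectory(frames=frame[None], box=patch.box, patch=patch,
                          params=ForceFieldParams())

    def test_axis_aligned_strands(self, tiny_patch):
        stats = glycan_angle_stats(self._line_trajectory(tiny_patch))
        assert stats.mean == pytest.approx(0.0, abs=1e-9)
        assert stats.std == pytest.approx(0.0, abs=1e-9)

    def test_two_point_distribution(self):
        cfg = PatchConfig(mean_length=5, sd_length=0, n_strands=2,
                          spacing=8.0, spacing_jitter=0.0,
                          randomize_offsets=False, seed=0, box_height=4.0)
        patch = generate_patch(cfg)
        # tilt strand 0 by +20 deg and strand 1 by -20 deg about z
        for sid, sign in ((0, 1.0), (1, -1.0)):
            s = patch.strands[sid]
            n = s.n_beads
            t = np.arange(n) * 0.515
            ang = np.radians(sign * 20.0)
            patch.positions[s.start:s.stop, 0] = t * np.cos(ang)
            patch.positions[s.start:s.stop, 1] = (
                sid * 8.0 + t * np.sin(ang))
        stats = glycan_angle_stats(self._line_trajectory(patch))
        assert stats.mean == pytest.approx(0.0, abs=1e-6)
        assert stats.std == pytest.approx(20.0, abs=1e-6)

    def test_invariance_under_translation_and_wrapping(self, tiny_patch):
        base = glycan_angle_stats(self._line_trajectory(tiny_patch))
        shifted = tiny_patch.copy()
        shifted.positions += np.array([1.7, 2.3, 0.4])
        shifted.stem_tip += np.array([1.7, 2.3, 0.4])
        shifted.wrap()
        stats = glycan_angle_stats(self._line_trajectory(shifted))
        assert stats.mean == pytest.approx(base.mean, abs=1e-9)
        assert stats.std == pytest.approx(base.std, abs=1e-9)

    def test_relaxed_patch_disorder_is_significant(self, small_relaxed_patch,
                                                   ff_params):
        rec, traj = measure_stress(small_relaxed_patch, ff_params,
                                   n_steps=400, seed=8,
                                   return_trajectory=True)
        stats = glycan_angle_stats(traj)
        assert stats.std > 3.0  # strand angles are visibly disordered


class TestUnitArea:
    def test_simple_division(self, tiny_patch):
        patch = tiny_patch.copy()
        patch.box[0] = 10.0
        patch.box[1] = 10.0
        # 40 disaccharides would give 2.5 nm^2; scale to the actual count
        assert unit_area(patch) == pytest.approx(
            100.0 / patch.n_disaccharides)

    def test_scaling_with_box_area(self, tiny_patch):
        doubled = tiny_patch.copy()
        doubled.box[0] *= 2
        doubled.box[1] *= 2
        assert unit_area(doubled) == pytest.approx(4 * unit_area(tiny_patch))


class TestStructureReportDirections:
    @pytest.fixture(scope="class")
    def reports(self, avg17_relaxed_patch, ff_params):
        out = {}
        for label, patch in (
                ("relaxed", avg17_relaxed_patch),
                ("strained", apply_strain(avg17_relaxed_patch,
                                          StrainSpec("glycan", 0.175)))):
            rec, traj = measure_stress(patch, ff_params, n_steps=2000,
                                       seed=42, return_trajectory=True)
            out[label] = structure_report(patch, traj, ff_params,
                                          pore_frame_stride=5)
        return out

    def test_thickness_decreases_under_strain(self, reports):
        assert reports["strained"].thickness_density < \
            reports["relaxed"].thickness_density

    def test_pore_radius_increases_under_strain(self, reports):
        assert reports["strained"].pore_radius > reports["relaxed"].pore_radius

    def test_unit_area_increases_under_stretch(self, reports):
        assert reports["strained"].unit_area > reports["relaxed"].unit_area

    def test_stress_thickness_not_larger_than_density_thickness(self,
                                                                reports):
        for rep in reports.values():
            if rep.thickness_stress is not None:
                assert rep.thickness_stress <= rep.thickness_density + 0.2
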