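"""Bead-spring energetics and Langevin dynamics for cell-wall patches.

The engine treats saccharide beads and stem tips as point particles in a
box periodic in x and y. Interactions: harmonic backbone bonds, a
(1 - cos) bending potential calibrated to the glycan persistence length,
a torsional potential keeping successive peptide stems near the native
inter-peptide angle, finitely extensible stem and cross-link springs
(harmonic below their contour length, stiff harmonic wall beyond), and a
soft, bounded pairwise repulsion for excluded volume.

Reduced units: energies in kBT, lengths in nm, masses in GlcNAc units.
Stress is accumulated as the internal pressure tensor and reported as
tensile stress (positive = tension) in MPa via the kBT/nm^3 -> MPa
conversion at the simulation temperature.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import units
from .cg_model import (Patch, discrete_bend_stiffness, MASS_STEM,
                       STEM_REST_LENGTH, SACCHARIDE_RISE)
from .records import (PressureProfile, StressStrainRecord, GLYCAN_AXIS,
                      axis_index)


class SimulationError(RuntimeError):
    """Raised when dynamics diverge or a protocol precondition fails."""


@dataclass(frozen=True)
class ForceFieldParams:
    """Coarse-grained force-field constants (energies in kBT, lengths nm).

    ``kappa_bend`` is the glycan bending modulus in kBT*nm; it equals the
    target persistence length in nm because lp = kappa/kBT for a worm-like
    chain. The per-joint stiffness of the discrete chain is derived from it
    by exact inversion of the discrete tangent-correlation relation.
    """
    k_bond: float = 1000.0          # backbone stretch, kBT/nm^2
    r0: float = SACCHARIDE_RISE     # saccharide rise, nm
    kappa_bend: float = 13.6        # kBT*nm; lp of an isolated strand
    k_phase: float = 1.0            # stem torsion, kBT/rad^2
    phase0_deg: float = 90.0        # native inter-peptide angle (4 per turn)
    k_stem: float = 1.5             # stem spring, kBT/nm^2
    stem_rest: float = STEM_REST_LENGTH
    stem_contour: float = 2.0       # nm; stiff wall beyond
    k_x: float = 2.0                # cross-link spring, kBT/nm^2
    x_rest: float = 0.5             # nm
    x_contour: float = 4.0          # nm
    ev_epsilon: float = 5.0         # excluded volume strength, kBT
    ev_sigma: float = 0.5           # excluded volume range, nm
    temperature: float = units.DEFAULT_TEMPERATURE_K
    gamma: float = 1.0              # Langevin friction, 1/tau
    dt: float = 0.005               # timestep, tau
    wall_factor: float = 100.0      # contour-wall stiffness multiplier

    def __post_init__(self):
        for name in ("k_bond", "kappa_bend", "k_phase", "k_stem", "k_x",
                     "ev_epsilon", "ev_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stem_contour < self.stem_rest or self.x_contour < self.x_rest:
            raise ValueError("contour length must be >= rest length")


@dataclass
class Trajectory:
    """Sampled particle positions (saccharide beads then stem tips)."""
    frames: np.ndarray            # (n_frames, n_particles, 3)
    box: np.ndarray               # (3,)
    patch: Patch
    params: ForceFieldParams
    sample_stride: int = 1

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def tip_frames(self) -> np.ndarray:
        """Stem-tip coordinates only, shape (n_frames, n_stems, 3)."""
        return self.frames[:, self.patch.n_beads:, :]

    def bead_frames(self) -> np.ndarray:
        return self.frames[:, :self.patch.n_beads, :]


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

class Topology:
    """Interaction tables derived from a Patch for a given force field."""

    def __init__(self, patch: Patch, params: ForceFieldParams):
        self.patch = patch
        self.params = params
        nb = patch.n_beads
        self.n_particles = nb + patch.n_stems

        self.masses = np.concatenate([
            patch.bead_masses, np.full(patch.n_stems, MASS_STEM)
        ]) / units.MASS_SCALE_DA

        eps_bend = discrete_bend_stiffness(params.kappa_bend, params.r0)

        bonds = []      # (i, j, k, r0, contour)
        angles = []     # (i, j, k) with the bend stiffness eps_bend
        dihedrals = []  # (a, b, c, d, phi0_rad)
        for sid, s in enumerate(patch.strands):
            idx = np.arange(s.start, s.stop)
            for a, b in zip(idx[:-1], idx[1:]):
                bonds.append((a, b, params.k_bond, params.r0, np.inf))
            trip = list(zip(idx[:-2], idx[1:-1], idx[2:]))
            if s.is_periodic:
                bonds.append((idx[-1], idx[0], params.k_bond, params.r0,
                              np.inf))
                trip.append((idx[-2], idx[-1], idx[0]))
                trip.append((idx[-1], idx[0], idx[1]))
            angles.extend(trip)

        # stem springs and torsions; the torsional minimum is the force
        # field's native periodicity, independent of the construction angle
        phi0 = math.radians(params.phase0_deg)
        stems_by_strand: dict[int, list[int]] = {}
        for si in range(patch.n_stems):
            anchor = int(patch.stem_anchor[si])
            tip = nb + si
            bonds.append((anchor, tip, params.k_stem, params.stem_rest,
                          params.stem_contour))
            stems_by_strand.setdefault(
                int(patch.strand_of_bead[anchor]), []).append(si)
        for sid, stems in stems_by_strand.items():
            stems = sorted(stems, key=lambda s: patch.index_in_strand[
                patch.stem_anchor[s]])
            pairs = list(zip(stems[:-1], stems[1:]))
            if patch.strands[sid].is_periodic and len(stems) > 2:
                pairs.append((stems[-1], stems[0]))
            for s1, s2 in pairs:
                a1, a2 = int(patch.stem_anchor[s1]), int(patch.stem_anchor[s2])
                dihedrals.append((nb + s1, a1, a2, nb + s2, phi0))

        for d, a, rest, cont in zip(patch.link_donor, patch.link_acceptor,
                                    patch.link_rest, patch.link_contour):
            bonds.append((nb + int(d), nb + int(a), params.k_x,
                          float(rest), float(cont)))

        self.bond_i = np.array([b[0] for b in bonds], dtype=int)
        self.bond_j = np.array([b[1] for b in bonds], dtype=int)
        self.bond_k = np.array([b[2] for b in bonds], dtype=float)
        self.bond_r0 = np.array([b[3] for b in bonds], dtype=float)
        self.bond_contour = np.array([b[4] for b in bonds], dtype=float)

        self.angles = np.array(angles, dtype=int).reshape(-1, 3)
        self.eps_bend = eps_bend

        self.dihedrals = np.array([d[:4] for d in dihedrals],
                                  dtype=int).reshape(-1, 4)
        self.dihedral_phi0 = np.array([d[4] for d in dihedrals], dtype=float)

        # bonded pairs excluded from the pairwise repulsion (packed keys)
        excl = set(zip(self.bond_i.tolist(), self.bond_j.tolist()))
        excl |= {(j, i) for i, j in excl}
        self.exclusions = excl
        n = self.n_particles
        self._excl_packed = np.array(sorted(i * n + j for i, j in excl),
                                     dtype=np.int64)
        # Verlet-style pair cache: rebuilt with a skin, pruned per call
        self._pair_cache: np.ndarray | None = None
        self._pair_age = 0
        self.pair_refresh_interval = 10
        self.pair_skin = 0.4

    def ev_candidate_pairs(self, positions: np.ndarray,
                           box: np.ndarray) -> np.ndarray:
        """Excluded-volume candidate pairs within cutoff + skin (cached)."""
        cutoff = self.params.ev_sigma + self.pair_skin
        if (self._pair_cache is None or
                self._pair_age >= self.pair_refresh_interval):
            pairs = _ev_pairs(positions, box, cutoff)
            if len(pairs):
                packed = pairs[:, 0].astype(np.int64) * self.n_particles \
                    + pairs[:, 1]
                keep = ~np.isin(packed, self._excl_packed,
                                assume_unique=False)
                pairs = pairs[keep]
            self._pair_cache = pairs
            self._pair_age = 0
        self._pair_age += 1
        return self._pair_cache

    def positions(self) -> np.ndarray:
        return np.vstack([self.patch.positions, self.patch.stem_tip])

    def write_back(self, positions: np.ndarray) -> None:
        """Store particle coordinates back into the patch arrays."""
        nb = self.patch.n_beads
        self.patch.positions[:] = positions[:nb]
        self.patch.stem_tip[:] = positions[nb:]
        self.patch.wrap()


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image convention in x and y; z is open."""
    d = d.copy()
    for ax in (0, 1):
        d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def _ev_pairs(pos: np.ndarray, box: np.ndarray, cutoff: float) -> np.ndarray:
    """Candidate close pairs under x/y periodicity via a padded KD-tree."""
    wrapped = pos.copy()
    wrapped[:, 0] %= box[0]
    wrapped[:, 1] %= box[1]
    zpad = 4.0 * (np.max(np.abs(wrapped[:, 2])) + cutoff + 1.0)
    wrapped[:, 2] += zpad / 2.0
    tree = cKDTree(wrapped, boxsize=[box[0], box[1], zpad])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def compute_forces(topology: Topology, positions: np.ndarray,
                   box: np.ndarray, return_arms: bool = False):
    """Total energy, per-particle forces, and diagonal virial.

    Returns ``(energy, forces, virial)`` where ``virial[a] = sum f_a * d_a``
    over all interaction arms (configurational part of the pressure tensor
    times volume). With ``return_arms=True`` additionally returns the list
    of per-interaction arms ``(ref_index, part_index, force_on_part, d)``
    with ``d`` the minimum-image displacement ref->participant, used for
    slab-resolved stress profiles.
    """
    p = topology.params
    n = len(positions)
    energy = 0.0
    forces = np.zeros((n, 3))
    virial = np.zeros(3)
    arms = [] if return_arms else None

    def add_arm(ref, part, f_part, d):
        nonlocal virial
        virial += np.sum(f_part * d, axis=0) if f_part.ndim == 2 else f_part * d
        if arms is not None:
            if f_part.ndim == 2:
                arms.append((np.asarray(ref), np.asarray(part), f_part, d))
            else:
                arms.append((np.array([ref]), np.array([part]),
                             f_part[None], d[None]))

    # -- bonds (harmonic + contour wall) -----------------------------------
    if len(topology.bond_i):
        bi, bj = topology.bond_i, topology.bond_j
        d = _min_image(positions[bj] - positions[bi], box)
        r = np.linalg.norm(d, axis=1)
        r_safe = np.where(r < 1e-12, 1e-12, r)
        dr = r - topology.bond_r0
        energy += float(np.sum(0.5 * topology.bond_k * dr * dr))
        fmag = -topology.bond_k * dr        # along +d on particle j
        over = r > topology.bond_contour
        if np.any(over):
            kw = p.wall_factor * topology.bond_k[over]
            dw = r[over] - topology.bond_contour[over]
            energy += float(np.sum(0.5 * kw * dw * dw))
            fmag[over] -= kw * dw
        fj = (fmag / r_safe)[:, None] * d
        np.add.at(forces, bj, fj)
        np.add.at(forces, bi, -fj)
        add_arm(bi, bj, fj, d)

    # -- bending: U = eps * (1 - cos theta) per interior joint -------------
    if len(topology.angles):
        ai, aj, ak = topology.angles.T
        u1 = _min_image(positions[aj] - positions[ai], box)
        u2 = _min_image(positions[ak] - positions[aj], box)
        n1 = np.linalg.norm(u1, axis=1)
        n2 = np.linalg.norm(u2, axis=1)
        inv12 = 1.0 / (n1 * n2)
        cos = np.sum(u1 * u2, axis=1) * inv12
        cos = np.clip(cos, -1.0, 1.0)
        energy += float(topology.eps_bend * np.sum(1.0 - cos))
        # dU/du1 and dU/du2 for U = -eps*cos
        dcos_du1 = inv12[:, None] * u2 - (cos / n1 ** 2)[:, None] * u1
        dcos_du2 = inv12[:, None] * u1 - (cos / n2 ** 2)[:, None] * u2
        # F = -grad U with U = eps*(1-cos); du1/dri = -I, du2/drk = +I
        fi = -topology.eps_bend * dcos_du1
        fk = topology.eps_bend * dcos_du2
        fj = -(fi + fk)
        np.add.at(forces, ai, fi)
        np.add.at(forces, aj, fj)
        np.add.at(forces, ak, fk)
        add_arm(aj, ai, fi, -u1)
        add_arm(aj, ak, fk, u2)

    # -- stem torsions ------------------------------------------------------
    if len(topology.dihedrals):
        a, b, c, dd = topology.dihedrals.T
        b1 = _min_image(positions[b] - positions[a], box)
        b2 = _min_image(positions[c] - positions[b], box)
        b3 = _min_image(positions[dd] - positions[c], box)
        n1v = np.cross(b1, b2)
        n2v = np.cross(b2, b3)
        n1sq = np.sum(n1v * n1v, axis=1)
        n2sq = np.sum(n2v * n2v, axis=1)
        b2n = np.linalg.norm(b2, axis=1)
        ok = (n1sq > 1e-18) & (n2sq > 1e-18) & (b2n > 1e-12)
        x = np.sum(n1v * n2v, axis=1)
        y = np.sum(np.cross(n1v, n2v) * b2, axis=1) / np.where(b2n, b2n, 1.0)
        phi = np.arctan2(y, x)
        dphi = phi - topology.dihedral_phi0
        dphi = (dphi + np.pi) % (2.0 * np.pi) - np.pi
        energy += float(np.sum(np.where(ok, p.k_phase * dphi * dphi, 0.0)))
        dU = np.where(ok, 2.0 * p.k_phase * dphi, 0.0)
        dphi_da = -(b2n / np.where(n1sq, n1sq, 1.0))[:, None] * n1v
        dphi_dd = (b2n / np.where(n2sq, n2sq, 1.0))[:, None] * n2v
        t1 = (np.sum(b1 * b2, axis=1) / b2n ** 2)[:, None]
        t2 = (np.sum(b3 * b2, axis=1) / b2n ** 2)[:, None]
        dphi_db = -(1.0 + t1) * dphi_da + t2 * dphi_dd
        dphi_dc = t1 * dphi_da - (1.0 + t2) * dphi_dd
        fa = -dU[:, None] * dphi_da
        fb = -dU[:, None] * dphi_db
        fc = -dU[:, None] * dphi_dc
        fd = -dU[:, None] * dphi_dd
        np.add.at(forces, a, fa)
        np.add.at(forces, b, fb)
        np.add.at(forces, c, fc)
        np.add.at(forces, dd, fd)
        add_arm(b, a, fa, -b1)
        add_arm(b, c, fc, b2)
        add_arm(b, dd, fd, b2 + b3)

    # -- excluded volume: U = eps*(1 - r/sigma)^2, bounded at r=0 ----------
    pairs = topology.ev_candidate_pairs(positions, box)
    if len(pairs):
        pi, pj = pairs[:, 0], pairs[:, 1]
        d = _min_image(positions[pj] - positions[pi], box)
        r = np.linalg.norm(d, axis=1)
        inside = r < p.ev_sigma
        pi, pj, d, r = pi[inside], pj[inside], d[inside], r[inside]
        if len(r):
            r_safe = np.where(r < 1e-9, 1e-9, r)
            x = 1.0 - r / p.ev_sigma
            energy += float(p.ev_epsilon * np.sum(x * x))
            fmag = 2.0 * p.ev_epsilon * x / p.ev_sigma  # repulsive, on j: +d
            fj = (fmag / r_safe)[:, None] * d
            np.add.at(forces, pj, fj)
            np.add.at(forces, pi, -fj)
            add_arm(pi, pj, fj, d)

    if arms is not None:
        return energy, forces, virial, arms
    return energy, forces, virial


def energy_and_forces(patch: Patch, params: ForceFieldParams):
    """Total potential energy (kBT) and per-particle forces (kBT/nm)."""
    topo = Topology(patch, params)
    e, f, _ = compute_forces(topo, topo.positions(), patch.box)
    return e, f


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def langevin_run(topology: Topology, n_steps: int, seed: int | None = 0,
                 frozen: np.ndarray | None = None,
                 sample_stride: int = 10,
                 velocities: np.ndarray | None = None,
                 callback=None):
    """BAOAB Langevin integration at kBT = 1.

    ``frozen`` is a boolean mask of immobilized particles. ``callback`` is
    invoked as ``callback(step, positions, velocities, virial)`` at every
    sampling stride. Returns the sampled frames, final positions, and final
    velocities. With ``gamma == 0`` this reduces to velocity Verlet.
    """
    p = topology.params
    box = topology.patch.box
    pos = topology.positions().astype(float)
    n = len(pos)
    m = topology.masses[:, None]
    rng = np.random.default_rng(seed)
    if velocities is None:
        vel = rng.normal(size=(n, 3)) / np.sqrt(m)
    else:
        vel = velocities.copy()
    if frozen is None:
        frozen = np.zeros(n, dtype=bool)
    vel[frozen] = 0.0

    c1 = math.exp(-p.gamma * p.dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))

    _, forces, virial = compute_forces(topology, pos, box)
    frames = [pos.copy()]
    if callback is not None:
        callback(0, pos, vel, virial)
    for step in range(1, n_steps + 1):
        vel += 0.5 * p.dt * forces / m
        vel[frozen] = 0.0
        pos += 0.5 * p.dt * vel
        if p.gamma > 0:
            vel = c1 * vel + c2 * rng.normal(size=(n, 3)) / np.sqrt(m)
            vel[frozen] = 0.0
        pos += 0.5 * p.dt * vel
        e, forces, virial = compute_forces(topology, pos, box)
        if not np.isfinite(e) or e > 1e12:
            raise SimulationError(f"dynamics diverged at step {step}: E={e}")
        vel += 0.5 * p.dt * forces / m
        vel[frozen] = 0.0
        if step % sample_stride == 0:
            frames.append(pos.copy())
            if callback is not None:
                callback(step, pos, vel, virial)
    return np.array(frames), pos, vel


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    return 0.5 * float(np.sum(masses[:, None] * velocities ** 2))


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def _instantaneous_pressure(topology, pos, vel, virial, volume):
    """Diagonal pressure tensor (kBT/nm^3): kinetic + configurational."""
    kin = np.sum(topology.masses[:, None] * vel * vel, axis=0)
    return (kin + virial) / volume


def relax_patch(patch: Patch, params: ForceFieldParams, n_steps: int = 4000,
                seed: int = 0, baro_interval: int = 20, gain: float = 0.05,
                max_step: float = 0.002):
    """Relax a linked patch to its equilibrium in-plane box dimensions.

    Langevin dynamics with a proportional in-plane barostat: every
    ``baro_interval`` steps Lx and Ly are rescaled toward zero time-averaged
    in-plane stress (z is open and unregulated). The relaxed dimensions are
    the average of the box series over the final half of the run.
    Returns ``(relaxed_patch, box_series)``.
    """
    if patch.n_links == 0:
        raise SimulationError("relax_patch expects a cross-linked patch")
    patch = patch.copy()
    topo = Topology(patch, params)
    p = params
    box = patch.box
    pos = topo.positions().astype(float)
    rng = np.random.default_rng(seed)
    m = topo.masses[:, None]
    vel = rng.normal(size=pos.shape) / np.sqrt(m)
    c1 = math.exp(-p.gamma * p.dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    volume = box[0] * box[1] * box[2]

    _, forces, virial = compute_forces(topo, pos, box)
    box_series = [box[:2].copy()]
    acc = np.zeros(3)
    n_acc = 0
    for step in range(1, n_steps + 1):
        vel += 0.5 * p.dt * forces / m
        pos += 0.5 * p.dt * vel
        vel = c1 * vel + c2 * rng.normal(size=pos.shape) / np.sqrt(m)
        pos += 0.5 * p.dt * vel
        e, forces, virial = compute_forces(topo, pos, box)
        if not np.isfinite(e) or e > 1e12:
            raise SimulationError(f"relaxation diverged at step {step}")
        vel += 0.5 * p.dt * forces / m
        acc += _instantaneous_pressure(topo, pos, vel, virial, volume)
        n_acc += 1
        if step % baro_interval == 0:
            pressure = acc / n_acc       # positive = pushes outward
            acc[:] = 0.0
            n_acc = 0
            for ax in (0, 1):
                strain_step = float(np.clip(gain * pressure[ax],
                                            -max_step, max_step))
                box[ax] *= (1.0 + strain_step)
                pos[:, ax] *= (1.0 + strain_step)
            volume = box[0] * box[1] * box[2]
            box_series.append(box[:2].copy())

    box_series = np.array(box_series)
    tail = box_series[len(box_series) // 2:]
    relaxed = tail.mean(axis=0)
    scale = relaxed / box[:2]
    pos[:, :2] *= scale
    box[:2] = relaxed
    topo.write_back(pos)
    return patch, box_series


@dataclass(frozen=True)
class StrainSpec:
    """A clamped uniaxial in-plane strain: stretch one axis, clamp the other."""
    axis: str           # 'glycan' (x) or 'peptide' (y)
    epsilon: float

    def __post_init__(self):
        axis_index(self.axis)
        if self.epsilon < 0:
            raise ValueError("strain must be non-negative")


def apply_strain(patch: Patch, spec: StrainSpec) -> Patch:
    """Affinely stretch one in-plane box dimension by (1 + epsilon)."""
    out = patch.copy()
    ax = axis_index(spec.axis)
    factor = 1.0 + spec.epsilon
    out.box[ax] *= factor
    out.positions[:, ax] *= factor
    out.stem_tip[:, ax] *= factor
    return out


def strain_sweep_specs(n_per_axis: int = 6) -> list[StrainSpec]:
    """The clamped-strain protocol: glycan 1.25-17.5%, peptide 5-45%."""
    specs = [StrainSpec("glycan", e)
             for e in np.linspace(0.0125, 0.175, n_per_axis)]
    specs += [StrainSpec("peptide", e)
              for e in np.linspace(0.05, 0.45, n_per_axis)]
    return specs


def measure_stress(patch: Patch, params: ForceFieldParams,
                   n_steps: int = 2000, seed: int = 0, h_eff: float = 4.0,
                   axis: str = GLYCAN_AXIS, epsilon: float = 0.0,
                   equil_fraction: float = 0.3,
                   return_trajectory: bool = False):
    """Time-averaged in-plane tensile stress of a patch, in MPa.

    The pressure tensor (kinetic + configurational virial, minimum-image
    convention) is averaged after discarding the first ``equil_fraction``
    of the run; tensile stress is its negative, converted to MPa using the
    cross-section (transverse box length x ``h_eff``), i.e. the effective
    volume Lx*Ly*h_eff.
    """
    if h_eff <= 0:
        raise ValueError("h_eff must be positive")
    topo = Topology(patch, params)
    volume = patch.box[0] * patch.box[1] * h_eff
    n_skip = int(equil_fraction * n_steps)
    samples = []

    def cb(step, pos, vel, virial):
        if step >= n_skip:
            samples.append(_instantaneous_pressure(topo, pos, vel, virial,
                                                   volume))

    frames, pos, _ = langevin_run(topo, n_steps, seed=seed, callback=cb,
                                  sample_stride=max(1, n_steps // 200))
    pressure = np.mean(samples, axis=0)
    tension = -pressure
    sigma_g = units.stress_kbt_to_mpa(float(tension[0]), params.temperature)
    sigma_p = units.stress_kbt_to_mpa(float(tension[1]), params.temperature)
    record = StressStrainRecord(
        axis=axis, epsilon=epsilon, sigma_g=sigma_g, sigma_p=sigma_p,
        h_eff=h_eff, n_steps=n_steps, seed=seed,
        short_averaging=len(samples) < 50)
    if return_trajectory:
        traj = Trajectory(frames=frames, box=patch.box.copy(), patch=patch,
                          params=params,
                          sample_stride=max(1, n_steps // 200))
        return record, traj
    return record


def virial_stress_components(patch: Patch, params: ForceFieldParams,
                             velocities: np.ndarray | None = None,
                             h_eff: float = 4.0):
    """One-shot kinetic and configurational pressure components (kBT/nm^3).

    With ``velocities=None`` the kinetic part is the equipartition
    expectation N*kBT/V per diagonal component.
    """
    topo = Topology(patch, params)
    pos = topo.positions()
    _, _, virial = compute_forces(topo, pos, patch.box)
    volume = patch.box[0] * patch.box[1] * h_eff
    if velocities is None:
        kin = np.full(3, topo.n_particles)  # sum m<v^2> = N kBT per axis
    else:
        kin = np.sum(topo.masses[:, None] * velocities ** 2, axis=0)
    return {"kinetic": kin / volume, "configurational": virial / volume,
            "pressure": (kin + virial) / volume}


# ---------------------------------------------------------------------------
# slab-resolved stress
# ---------------------------------------------------------------------------

def _distribute_segments(edges: np.ndarray, z0: np.ndarray, z1: np.ndarray,
                         weights: np.ndarray, out: np.ndarray) -> None:
    """Spread each weight over slabs proportionally to segment overlap."""
    lo = np.minimum(z0, z1)
    hi = np.maximum(z0, z1)
    span = hi - lo
    point = span < 1e-12
    if np.any(point):
        idx = np.clip(np.searchsorted(edges, lo[point], side="right") - 1,
                      0, len(out) - 1)
        np.add.at(out, idx, weights[point])
    seg = ~point
    if np.any(seg):
        overlap = np.clip(
            np.minimum(edges[None, 1:], hi[seg, None]) -
            np.maximum(edges[None, :-1], lo[seg, None]), 0.0, None)
        out += (weights[seg] / span[seg]) @ overlap


def pressure_profile(trajectory: Trajectory, axis: int = 2,
                     slab_width: float = 0.1,
                     component: str = "in_plane",
                     smooth_window: float = 0.5) -> PressureProfile:
    """Per-slab in-plane tensile stress along ``axis`` (Irving-Kirkwood).

    Bonded and pairwise contributions are distributed over slabs in
    proportion to the fraction of each interaction arm inside the slab; the
    kinetic part (equipartition expectation, kBT per particle per axis) is
    assigned to the slab containing the particle. The profile is smoothed
    with a running average of width ``smooth_window`` (0 disables).

    ``component``: 'in_plane' (mean of xx and yy), 'xx', or 'yy'.
    """
    if trajectory.n_frames < 1:
        raise ValueError("trajectory must contain at least one frame")
    patch, params = trajectory.patch, trajectory.params
    box = trajectory.box
    comp_axes = {"in_plane": (0, 1), "xx": (0,), "yy": (1,)}[component]
    topo = Topology(patch, params)

    if axis == 2:
        zs = trajectory.frames[:, :, 2]
        lo = float(zs.min()) - 2 * slab_width
        hi = float(zs.max()) + 2 * slab_width
    else:
        lo, hi = 0.0, float(box[axis])
    n_slabs = max(3, int(math.ceil((hi - lo) / slab_width)))
    if axis != 2 and slab_width > box[axis]:
        raise ValueError("slab_width larger than the box")
    edges = np.linspace(lo, hi, n_slabs + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = np.zeros(n_slabs)

    for frame in trajectory.frames:
        _, _, _, arms = compute_forces(topo, frame, box, return_arms=True)
        for ref, part, f, d in arms:
            w = np.zeros(len(f))
            for ca in comp_axes:
                w += f[:, ca] * d[:, ca]
            w /= len(comp_axes)
            z_ref = frame[ref, axis]
            _distribute_segments(edges, z_ref, z_ref + d[:, axis], w, acc)
        # kinetic: kBT per particle per diagonal component
        zp = frame[:, axis]
        idx = np.clip(np.searchsorted(edges, zp, side="right") - 1,
                      0, n_slabs - 1)
        np.add.at(acc, idx, 1.0)

    slab_vol = (box[0] * box[1] * box[2] / box[axis]) * (edges[1] - edges[0])
    pressure = acc / (trajectory.n_frames * slab_vol)
    stress = np.array([units.stress_kbt_to_mpa(-p, params.temperature)
                       for p in pressure])
    if smooth_window > 0:
        w = max(1, int(round(smooth_window / (edges[1] - edges[0]))))
        kernel = np.ones(w) / w
        stress = np.convolve(stress, kernel, mode="same")
    return PressureProfile(centers=centers, stress=stress,
                           slab_width=edges[1] - edges[0], axis=axis)
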