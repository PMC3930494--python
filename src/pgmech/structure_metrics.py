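"""Structural observables of cell-wall patches and glycan strands.

Covers the tangent-correlation persistence-length estimator, the
inter-peptide rotation series, both thickness definitions (mass-density
width and stress-bearing width at 10% of peak), the periodic
maximum-inscribed-circle pore radius, glycan strand-angle disorder, and
the area per disaccharide.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cg_model import Patch, WLCEnsemble, MASS_STEM
from .records import DensityProfile, PressureProfile


@dataclass
class AngleStats:
    """Signed in-plane strand-angle statistics, degrees."""
    mean: float
    std: float
    n_vectors: int

    def __post_init__(self):
        if not (-90.0 < self.mean <= 90.0):
            raise ValueError("mean angle must lie in (-90, 90]")
        if self.std < 0:
            raise ValueError("std must be >= 0")


@dataclass
class PoreResult:
    """Largest empty circle in the periodic x-y projection."""
    radius: float            # nm (time-averaged when over a trajectory)
    center: np.ndarray       # (2,) nm, for the best single frame
    per_frame_radii: np.ndarray | None = None

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("pore radius must be >= 0")


@dataclass
class StructureReport:
    """All structural metrics for one patch / strain state."""
    thickness_density: float       # nm
    thickness_stress: float | None  # nm; None when not estimable
    angle: AngleStats
    pore_radius: float             # nm
    unit_area: float               # nm^2 per disaccharide
    strain_axis: str | None = None
    strain: float = 0.0


# ---------------------------------------------------------------------------
# persistence length
# ---------------------------------------------------------------------------

def tangent_correlation(conformations: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean tangent correlation <cos theta(k)> over all starting positions.

    ``conformations`` has shape (n_chains_or_frames, n_points, 3). Returns
    the correlation for separations k = 1 .. n_points-2 and the mean
    segment length.
    """
    conf = np.asarray(conformations, dtype=float)
    if conf.ndim == 2:
        conf = conf[None]
    seg = np.diff(conf, axis=1)
    seg_len = np.linalg.norm(seg, axis=2)
    b = float(seg_len.mean())
    t = seg / seg_len[..., None]
    n_seg = t.shape[1]
    corr = np.empty(n_seg - 1)
    for k in range(1, n_seg):
        corr[k - 1] = float(np.mean(np.sum(t[:, :-k] * t[:, k:], axis=2)))
    return corr, b


def persistence_length(data, fit_cutoff: float | None = None):
    """Persistence length from the initial decay of <cos theta(s)>.

    ``data`` is a :class:`WLCEnsemble` or an array of chain conformations
    (frames of a simulated strand work the same way). The log-correlation
    is fitted against the contour separation s, through the origin, over
    the initial decay: s <= ``fit_cutoff`` when given, otherwise up to the
    first separation where the correlation drops below 1/e (at least three
    points). Returns -1/slope in nm, or ``None`` when there is no decay.
    """
    if isinstance(data, WLCEnsemble):
        conf = data.chains
    else:
        conf = np.asarray(data, dtype=float)
        if conf.ndim == 2:
            conf = conf[None]
    if conf.shape[1] - 1 < 10:
        raise ValueError("chains must have at least 10 segments")
    corr, b = tangent_correlation(conf)
    s = b * np.arange(1, len(corr) + 1)

    if fit_cutoff is not None:
        use = s <= fit_cutoff
    else:
        below = np.nonzero(corr < math.exp(-1.0))[0]
        k_max = below[0] + 1 if len(below) else len(corr)
        use = np.arange(len(corr)) < max(k_max, 3)
    use &= corr > 0
    if int(np.sum(use)) < 3:
        raise ValueError("fewer than 3 usable separations for the fit")
    su, lu = s[use], np.log(corr[use])
    slope = float(np.sum(su * lu) / np.sum(su * su))
    if slope >= -1e-6:
        return None  # straight within resolution: not estimable
    return -1.0 / slope


# ---------------------------------------------------------------------------
# peptide periodicity
# ---------------------------------------------------------------------------

def _dihedral_from_bonds(b1, b2, b3):
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2, axis=-1) / np.where(b2n, b2n, 1.0)
    return np.degrees(np.arctan2(y, x))


def _min_image_xy(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = d.copy()
    for ax in (0, 1):
        d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def _dihedral(p0, p1, p2, p3, box=None):
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    if box is not None:
        b1, b2, b3 = (_min_image_xy(b, box) for b in (b1, b2, b3))
    return _dihedral_from_bonds(b1, b2, b3)


def peptide_angle_series(trajectory) -> np.ndarray:
    """Mean |rotation| between successive stems about the strand axis.

    For each frame, the dihedral tip_i - anchor_i - anchor_{i+1} - tip_{i+1}
    is evaluated for every successive stem pair along each strand and the
    magnitudes are averaged; returns one value (degrees) per frame.
    """
    patch = trajectory.patch
    if patch.n_stems < 3:
        raise ValueError("need at least 3 stems")
    nb = patch.n_beads
    quads = []
    stem_strand = patch.strand_of_bead[patch.stem_anchor]
    for sid in range(patch.n_strands):
        stems = np.nonzero(stem_strand == sid)[0]
        stems = stems[np.argsort(patch.index_in_strand[
            patch.stem_anchor[stems]])]
        for s1, s2 in zip(stems[:-1], stems[1:]):
            quads.append((nb + s1, patch.stem_anchor[s1],
                          patch.stem_anchor[s2], nb + s2))
    quads = np.array(quads, dtype=int)
    out = np.empty(trajectory.n_frames)
    box = trajectory.box
    for f, frame in enumerate(trajectory.frames):
        phi = _dihedral(frame[quads[:, 0]], frame[quads[:, 1]],
                        frame[quads[:, 2]], frame[quads[:, 3]], box=box)
        out[f] = float(np.mean(np.abs(phi)))
    return out


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

def density_profile(trajectory, bin_width: float = 0.1) -> DensityProfile:
    """Mass-weighted z histogram averaged over frames, Da/nm^3."""
    patch = trajectory.patch
    frames = trajectory.frames
    if frames.shape[0] < 1:
        raise ValueError("empty trajectory")
    masses = np.concatenate([patch.bead_masses,
                             np.full(patch.n_stems, MASS_STEM)])
    z = frames[:, :, 2].ravel()
    w = np.tile(masses, frames.shape[0])
    lo = float(z.min()) - bin_width
    hi = float(z.max()) + bin_width
    n = max(3, int(math.ceil((hi - lo) / bin_width)))
    hist, edges = np.histogram(z, bins=n, range=(lo, hi), weights=w)
    slab_vol = patch.box[0] * patch.box[1] * (edges[1] - edges[0])
    density = hist / (frames.shape[0] * slab_vol)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(z=centers, density=density,
                          bin_width=edges[1] - edges[0])


def _width_at_fraction(x: np.ndarray, y: np.ndarray,
                       fraction: float) -> float | None:
    """Outermost width where y crosses fraction*max(y), interpolated."""
    peak = float(np.max(y))
    if peak <= 0:
        return None
    level = fraction * peak
    above = y >= level
    if not np.any(above):
        return None
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    # left crossing: interpolate between i0-1 (below) and i0 (above)
    if i0 == 0:
        left = x[0]
    else:
        y0, y1 = y[i0 - 1], y[i0]
        left = x[i0 - 1] + (level - y0) / (y1 - y0) * (x[i0] - x[i0 - 1])
    if i1 == len(y) - 1:
        right = x[-1]
    else:
        y0, y1 = y[i1], y[i1 + 1]
        right = x[i1] + (level - y0) / (y1 - y0) * (x[i1 + 1] - x[i1])
    return float(right - left)


def thickness_from_density(profile: DensityProfile) -> float:
    """Width of the mass-density profile at 10% of its peak, nm."""
    if len(profile.density) == 0 or np.max(profile.density) <= 0:
        raise ValueError("empty density profile")
    w = _width_at_fraction(profile.z, profile.density, 0.10)
    assert w is not None
    return w


def thickness_from_stress(profile: PressureProfile,
                          baseline_fraction: float = 0.2) -> float | None:
    """Stress-bearing width at 10% of the baseline-subtracted peak, nm.

    The far-field baseline is the mean over the outer ``baseline_fraction``
    of slabs (split between both ends). Returns ``None`` when no positive
    peak remains after baseline subtraction.
    """
    y = profile.stress.astype(float)
    n_edge = max(1, int(round(0.5 * baseline_fraction * len(y))))
    baseline = float(np.mean(np.concatenate([y[:n_edge], y[-n_edge:]])))
    excess = y - baseline
    if np.max(excess) <= 0:
        return None
    return _width_at_fraction(profile.centers, excess, 0.10)


# ---------------------------------------------------------------------------
# pores
# ---------------------------------------------------------------------------

def max_pore_radius(points, box_xy, bead_radius: float = 0.25,
                    resolution: float = 0.1, refine: bool = True
                    ) -> PoreResult:
    """Largest circle empty of bead disks in the periodic x-y plane.

    Candidate centers are laid on a grid of the given ``resolution``; the
    radius at a center is its minimum periodic distance to any bead minus
    ``bead_radius`` (clipped at zero). With ``refine`` a second, 10x finer
    local grid is searched around the best coarse candidate.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    pts = np.asarray(points, dtype=float)[:, :2].copy()
    if len(pts) == 0:
        raise ValueError("need at least one bead")
    box_xy = np.asarray(box_xy, dtype=float)
    pts %= box_xy
    tree = cKDTree(pts, boxsize=box_xy)

    def best_on(grid):
        d, _ = tree.query(grid)
        k = int(np.argmax(d))
        return float(d[k]), grid[k]

    nx = max(1, int(math.ceil(box_xy[0] / resolution)))
    ny = max(1, int(math.ceil(box_xy[1] / resolution)))
    gx = (np.arange(nx) + 0.5) * box_xy[0] / nx
    gy = (np.arange(ny) + 0.5) * box_xy[1] / ny
    grid = np.array(np.meshgrid(gx, gy)).reshape(2, -1).T
    d_best, c_best = best_on(grid)

    if refine:
        step = resolution / 10.0
        local = np.arange(-resolution, resolution + step / 2, step)
        sub = (c_best[None] +
               np.array(np.meshgrid(local, local)).reshape(2, -1).T)
        sub %= box_xy
        d_ref, c_ref = best_on(sub)
        if d_ref > d_best:
            d_best, c_best = d_ref, c_ref

    return PoreResult(radius=max(d_best - bead_radius, 0.0),
                      center=np.asarray(c_best))


def patch_pore_points(patch: Patch, frame: np.ndarray | None = None
                      ) -> np.ndarray:
    """x-y projection of all wall particles (beads and stem tips)."""
    if frame is None:
        return np.vstack([patch.positions, patch.stem_tip])[:, :2]
    return frame[:, :2]


def max_pore_radius_trajectory(trajectory, bead_radius: float = 0.25,
                               resolution: float = 0.1,
                               frame_stride: int = 1) -> PoreResult:
    """Per-frame maximum pore radius, then the time average."""
    box_xy = trajectory.box[:2]
    radii = []
    best = None
    for frame in trajectory.frames[::frame_stride]:
        res = max_pore_radius(frame[:, :2], box_xy, bead_radius, resolution)
        radii.append(res.radius)
        if best is None or res.radius > best.radius:
            best = res
    radii = np.asarray(radii)
    return PoreResult(radius=float(radii.mean()), center=best.center,
                      per_frame_radii=radii)


# ---------------------------------------------------------------------------
# strand-angle disorder
# ---------------------------------------------------------------------------

def unwrap_strand(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap a strand's bead coordinates via cumulative minimum image."""
    d = np.diff(positions, axis=0)
    for ax in (0, 1):
        d[:, ax] -= box[ax] * np.round(d[:, ax] / box[ax])
    out = np.empty_like(positions)
    out[0] = positions[0]
    out[1:] = positions[0] + np.cumsum(d, axis=0)
    return out


def _signed_angle_deg(vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    """Angle of (vx, vy) with the +x axis, folded into (-90, 90]."""
    ang = np.degrees(np.arctan2(vy, vx))
    ang = (ang + 90.0) % 180.0 - 90.0
    return np.where(ang == -90.0, 90.0, ang)


def glycan_angle_stats(trajectory, min_separation: int = 4) -> AngleStats:
    """Disorder of strand segments relative to the circumferential (+x) axis.

    For every within-strand bead pair at index separation >=
    ``min_separation`` the signed angle between the x-y projection of the
    connecting vector and +x is measured. Strand means are pooled (each
    strand weighted equally per frame) for the reported mean; the standard
    deviation is over all individual vectors.
    """
    patch = trajectory.patch
    box = trajectory.box
    strand_means = []
    all_angles = []
    for frame in trajectory.frames:
        for s in patch.strands:
            n = s.n_beads
            if n < min_separation + 1:
                continue
            pos = unwrap_strand(frame[s.start:s.stop], box)
            angles = []
            for sep in range(min_separation, n):
                v = pos[sep:] - pos[:-sep]
                angles.append(_signed_angle_deg(v[:, 0], v[:, 1]))
            angles = np.concatenate(angles)
            strand_means.append(float(np.mean(angles)))
            all_angles.append(angles)
    if not all_angles:
        raise ValueError("no eligible bead pairs "
                         f"(need strands > {min_separation} saccharides)")
    all_angles = np.concatenate(all_angles)
    mean = float(np.mean(strand_means))
    if not (-90.0 < mean <= 90.0):
        mean = float(_signed_angle_deg(np.cos(np.radians(mean)),
                                       np.sin(np.radians(mean))))
    return AngleStats(mean=mean, std=float(np.std(all_angles)),
                      n_vectors=len(all_angles))


# ---------------------------------------------------------------------------
# unit area and report
# ---------------------------------------------------------------------------

def unit_area(patch: Patch) -> float:
    """In-plane box area per disaccharide, nm^2."""
    n_ds = patch.n_disaccharides
    if n_ds <= 0:
        raise ValueError("patch contains no disaccharides")
    return float(patch.box[0] * patch.box[1] / n_ds)


def structure_report(patch: Patch, trajectory, params=None,
                     strain_axis: str | None = None, strain: float = 0.0,
                     bead_radius: float = 0.25, pore_resolution: float = 0.1,
                     density_bin: float = 0.1,
                     pore_frame_stride: int = 1) -> StructureReport:
    """Assemble every structural metric for one strain state."""
    from .mechanics_engine import pressure_profile
    dens = density_profile(trajectory, bin_width=density_bin)
    t_dens = thickness_from_density(dens)
    t_stress = None
    if params is not None:
        prof = pressure_profile(trajectory, axis=2, slab_width=density_bin)
        t_stress = thickness_from_stress(prof)
    angle = glycan_angle_stats(trajectory)
    pores = max_pore_radius_trajectory(trajectory, bead_radius,
                                       pore_resolution,
                                       frame_stride=pore_frame_stride)
    return StructureReport(
        thickness_density=t_dens, thickness_stress=t_stress, angle=angle,
        pore_radius=pores.radius, unit_area=unit_area(patch),
        strain_axis=strain_axis, strain=strain)
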