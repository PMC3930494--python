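"""Coarse-grained representation of peptidoglycan and synthetic-input generators.

The model uses one bead per saccharide (GlcNAc/MurNAc alternating along a
glycan strand, rise 0.515 nm) plus one effective tip bead per peptide stem,
anchored to its MurNAc by a spring. Strands run along x (the circumferential
/ glycan direction), rows are stacked along y (the axial / peptide
direction), and z is the wall normal. The box is periodic in x and y only.

Besides the patch builder this module provides the synthetic inputs used to
validate every downstream estimator: discrete worm-like-chain ensembles with
a known persistence length, analytic Gaussian density profiles, and a
noiseless forward model of the clamped-strain orthotropic stress response.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .records import (DensityProfile, ElasticModuli, StressStrainRecord,
                      GLYCAN_AXIS, PEPTIDE_AXIS, axis_index)

# bead kinds
GLCNAC = 0
MURNAC = 1
KIND_NAMES = {GLCNAC: "GlcNAc", MURNAC: "MurNAc"}

#: masses, Da
MASS_GLCNAC = 221.0
MASS_MURNAC = 275.0
#: effective stem mass, averaged over stems with/without the terminal D-Ala
MASS_STEM = 460.0

#: rise per saccharide along a glycan strand, nm (disaccharide ~ 1.03 nm)
SACCHARIDE_RISE = 0.515

#: stem rest length (anchor to effective tip), nm
STEM_REST_LENGTH = 1.0

# stem link states
STEM_FREE = 0
STEM_DONOR = 1
STEM_ACCEPTOR = 2


class ConfigurationError(ValueError):
    """Raised for invalid generator/builder configuration."""


class ConstructionError(RuntimeError):
    """Raised when a patch cannot be built from a valid configuration."""


# ---------------------------------------------------------------------------
# configuration and presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchConfig:
    """Parameters of one cell-wall patch construction.

    ``mean_length``/``sd_length`` are in disaccharides; strand rows are
    spaced ``spacing`` nm apart with per-row jitter of up to
    ``spacing_jitter`` nm. ``crosslink_target`` is the target fraction of
    peptide stems engaged in cross-links (~0.5 for E. coli).
    """
    mean_length: float = 17.0
    sd_length: float = 5.8
    n_strands: int = 12
    spacing: float = 2.5
    spacing_jitter: float = 0.5
    crosslink_target: float = 0.5
    saccharide_rise: float = SACCHARIDE_RISE
    inter_peptide_angle: float = 90.0   # degrees per MurNAc; 4 stems per turn
    periodic_strands: bool = False      # covalently closed across x ("inf")
    randomize_offsets: bool = True      # uniform random x-offset per strand
    box_height: float = 4.0             # nominal Lz, nm
    seed: int = 0
    preset_name: str = "custom"

    def __post_init__(self):
        if self.mean_length < 2:
            raise ConfigurationError("mean_length must be >= 2 disaccharides")
        if not (0.0 <= self.crosslink_target <= 1.0):
            raise ConfigurationError("crosslink_target must be in [0, 1]")
        if self.spacing_jitter < 0:
            raise ConfigurationError("spacing_jitter must be >= 0")
        if self.n_strands < 1:
            raise ConfigurationError("n_strands must be >= 1")
        if self.sd_length < 0:
            raise ConfigurationError("sd_length must be >= 0")
        if self.spacing <= 0 or self.saccharide_rise <= 0:
            raise ConfigurationError("spacing and saccharide_rise must be > 0")
        if self.periodic_strands and self.sd_length != 0:
            raise ConfigurationError(
                "periodic strands must have a fixed length (sd_length = 0)")


#: built-in constructions: mean +/- sd strand lengths in disaccharides.
#: Strand counts for avg17/avg26 follow the 12-strand construction; the
#: remaining counts approximate the corresponding relaxed row extents at
#: 2.5 nm spacing.
PRESETS: dict[str, PatchConfig] = {
    "avg8": PatchConfig(mean_length=8, sd_length=3.2, n_strands=7,
                        preset_name="avg8"),
    "avg17": PatchConfig(mean_length=17, sd_length=5.8, n_strands=12,
                         preset_name="avg17"),
    "avg26": PatchConfig(mean_length=26, sd_length=2.4, n_strands=12,
                         preset_name="avg26"),
    "inf15": PatchConfig(mean_length=15, sd_length=0.0, n_strands=5,
                         periodic_strands=True, randomize_offsets=True,
                         preset_name="inf15"),
    "inf30": PatchConfig(mean_length=30, sd_length=0.0, n_strands=10,
                         periodic_strands=True, randomize_offsets=True,
                         preset_name="inf30"),
}


def preset(name: str, **overrides) -> PatchConfig:
    """Return a built-in PatchConfig, optionally with fields overridden."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# patch data structures
# ---------------------------------------------------------------------------

@dataclass
class SaccharideBead:
    """View of one saccharide bead (one GlcNAc or MurNAc ring)."""
    position: np.ndarray
    kind: int
    strand_id: int
    index_in_strand: int

    @property
    def mass(self) -> float:
        return MASS_GLCNAC if self.kind == GLCNAC else MASS_MURNAC


@dataclass
class Strand:
    """Index range [start, stop) of one strand's beads in the patch arrays."""
    start: int
    stop: int
    is_periodic: bool = False

    @property
    def n_beads(self) -> int:
        return self.stop - self.start


@dataclass
class Patch:
    """A periodic, cross-linkable coarse-grained cell-wall patch.

    Arrays are the storage of record; ``SaccharideBead``/``Strand`` views
    are built on demand. Positions are wrapped into the primary box in x and
    y; z is open. Stem tips live in ``stem_tip`` and are dynamic degrees of
    freedom on a par with the saccharide beads.
    """
    box: np.ndarray                      # (3,) Lx, Ly, Lz in nm
    positions: np.ndarray                # (n_beads, 3)
    kinds: np.ndarray                    # (n_beads,) GLCNAC/MURNAC
    strand_of_bead: np.ndarray           # (n_beads,)
    index_in_strand: np.ndarray          # (n_beads,)
    strands: list[Strand]
    stem_anchor: np.ndarray              # (n_stems,) bead index (MurNAc)
    stem_phase: np.ndarray               # (n_stems,) degrees about +x
    stem_tip: np.ndarray                 # (n_stems, 3)
    stem_state: np.ndarray               # (n_stems,) STEM_FREE/DONOR/ACCEPTOR
    link_donor: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    link_acceptor: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    link_rest: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    link_contour: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    preset_name: str = "custom"
    config: PatchConfig | None = None

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_stems(self) -> int:
        return len(self.stem_anchor)

    @property
    def n_links(self) -> int:
        return len(self.link_donor)

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    @property
    def n_disaccharides(self) -> float:
        return self.n_beads / 2.0

    def bead(self, i: int) -> SaccharideBead:
        return SaccharideBead(self.positions[i], int(self.kinds[i]),
                              int(self.strand_of_bead[i]),
                              int(self.index_in_strand[i]))

    @property
    def bead_masses(self) -> np.ndarray:
        return np.where(self.kinds == GLCNAC, MASS_GLCNAC, MASS_MURNAC)

    def strand_beads(self, strand_id: int) -> np.ndarray:
        s = self.strands[strand_id]
        return np.arange(s.start, s.stop)

    def copy(self) -> "Patch":
        return Patch(
            box=self.box.copy(), positions=self.positions.copy(),
            kinds=self.kinds.copy(), strand_of_bead=self.strand_of_bead.copy(),
            index_in_strand=self.index_in_strand.copy(),
            strands=[Strand(s.start, s.stop, s.is_periodic)
                     for s in self.strands],
            stem_anchor=self.stem_anchor.copy(),
            stem_phase=self.stem_phase.copy(),
            stem_tip=self.stem_tip.copy(), stem_state=self.stem_state.copy(),
            link_donor=self.link_donor.copy(),
            link_acceptor=self.link_acceptor.copy(),
            link_rest=self.link_rest.copy(),
            link_contour=self.link_contour.copy(),
            preset_name=self.preset_name, config=self.config)

    def wrap(self) -> None:
        """Wrap all x/y coordinates into the primary box (z left open)."""
        for arr in (self.positions, self.stem_tip):
            arr[:, 0] %= self.box[0]
            arr[:, 1] %= self.box[1]

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        for s in self.strands:
            k = self.kinds[s.start:s.stop]
            if s.n_beads < 4 or s.n_beads % 2:
                raise ValueError("strand length must be even and >= 4")
            if not np.all(k[::2] == k[0]) or not np.all(k[1::2] != k[0]):
                raise ValueError("saccharide kinds must alternate")
            idx = self.index_in_strand[s.start:s.stop]
            if not np.array_equal(idx, np.arange(s.n_beads)):
                raise ValueError("index_in_strand must be 0-based contiguous")
        if self.n_stems != int(np.sum(self.kinds == MURNAC)):
            raise ValueError("exactly one stem per MurNAc bead required")
        linked = np.concatenate([self.link_donor, self.link_acceptor])
        if len(linked) != len(np.unique(linked)):
            raise ValueError("a stem may participate in at most one cross-link")
        if np.any(self.strand_of_bead[self.stem_anchor[self.link_donor]] ==
                  self.strand_of_bead[self.stem_anchor[self.link_acceptor]]):
            raise ValueError("cross-links must join different strands")


@dataclass
class WLCEnsemble:
    """Discrete worm-like chains with a known generating persistence length."""
    chains: np.ndarray      # (n_chains, n_points, 3)
    b: float                # segment length, nm
    generating_lp: float    # nm
    seed: int | None = None

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def n_segments(self) -> int:
        return self.chains.shape[1] - 1


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_strand_lengths(mean: float, sd: float, n: int,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw integer strand lengths (disaccharides) from a Gaussian.

    Draws are rounded to the nearest integer; draws below 2 disaccharides
    are redrawn so every strand contains at least two disaccharides.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if mean < 2:
        raise ConfigurationError("mean must be >= 2 disaccharides")
    if sd < 0:
        raise ConfigurationError("sd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    out = np.empty(n, dtype=int)
    todo = np.arange(n)
    while len(todo):
        draw = np.rint(rng.normal(mean, sd, size=len(todo))).astype(int)
        ok = draw >= 2
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def generate_patch(config: PatchConfig) -> Patch:
    """Lay out parallel, un-cross-linked strands according to ``config``.

    Strands run along +x at rows spaced ``config.spacing`` apart (with
    jitter), each with an optional uniform random x-offset and a random
    per-strand peptide phase offset; successive stems advance by
    ``inter_peptide_angle`` per MurNAc. No cross-links are created here.
    """
    rng = np.random.default_rng(config.seed)
    rise = config.saccharide_rise

    n_sacch_mean = 2 * config.mean_length
    if config.periodic_strands:
        lengths_ds = np.full(config.n_strands, int(round(config.mean_length)))
    else:
        lengths_ds = generate_strand_lengths(
            config.mean_length, config.sd_length, config.n_strands, rng)
    lengths_sacch = 2 * lengths_ds

    Ly = config.n_strands * config.spacing
    if config.periodic_strands:
        Lx = lengths_sacch[0] * rise   # strand spans the box exactly
        if np.any(lengths_sacch * rise > Lx + 1e-9):
            raise ConstructionError("periodic strand longer than the box")
    else:
        Lx = float(np.max(lengths_sacch - 1) * rise + config.spacing)
    box = np.array([Lx, Ly, config.box_height])

    positions, kinds, strand_of, idx_in = [], [], [], []
    strands: list[Strand] = []
    stem_anchor, stem_phase = [], []
    start = 0
    for i, n_sacch in enumerate(lengths_sacch):
        y = i * config.spacing + rng.uniform(-config.spacing_jitter,
                                             config.spacing_jitter)
        x0 = rng.uniform(0.0, Lx) if config.randomize_offsets else 0.0
        xs = x0 + np.arange(n_sacch) * rise
        pos = np.column_stack([xs, np.full(n_sacch, y), np.zeros(n_sacch)])
        positions.append(pos)
        k = np.arange(n_sacch) % 2  # G, M, G, M, ...
        kinds.append(k)
        strand_of.append(np.full(n_sacch, i))
        idx_in.append(np.arange(n_sacch))
        strands.append(Strand(start, start + n_sacch,
                              is_periodic=config.periodic_strands))
        # one stem per MurNAc, phase advancing along the strand
        murnac_local = np.nonzero(k == MURNAC)[0]
        phase0 = rng.uniform(0.0, 360.0)
        for j, m in enumerate(murnac_local):
            stem_anchor.append(start + m)
            stem_phase.append((phase0 + j * config.inter_peptide_angle) % 360.0)
        start += n_sacch

    positions = np.concatenate(positions)
    stem_anchor = np.asarray(stem_anchor, dtype=int)
    stem_phase = np.asarray(stem_phase, dtype=float)
    phase_rad = np.radians(stem_phase)
    tip_dir = np.column_stack([np.zeros_like(phase_rad),
                               np.cos(phase_rad), np.sin(phase_rad)])
    stem_tip = positions[stem_anchor] + STEM_REST_LENGTH * tip_dir

    patch = Patch(
        box=box, positions=positions,
        kinds=np.concatenate(kinds).astype(int),
        strand_of_bead=np.concatenate(strand_of).astype(int),
        index_in_strand=np.concatenate(idx_in).astype(int),
        strands=strands, stem_anchor=stem_anchor, stem_phase=stem_phase,
        stem_tip=stem_tip,
        stem_state=np.full(len(stem_anchor), STEM_FREE, dtype=int),
        preset_name=config.preset_name, config=config)
    patch.wrap()
    patch.validate()
    return patch


# -- worm-like chains -------------------------------------------------------

def discrete_bend_stiffness(lp: float, b: float) -> float:
    """Per-joint stiffness eps (kBT) of the U = eps*(1-cos theta) potential.

    Chosen by exact inversion of the discrete-chain relation
    <cos theta> = coth(eps) - 1/eps = exp(-b/lp), so a freely rotating
    discrete chain built with this stiffness has tangent correlations
    exp(-s/lp) exactly, i.e. persistence length lp.
    """
    if lp <= 0 or b <= 0:
        raise ConfigurationError("lp and b must be positive")
    target = math.exp(-b / lp)

    def f(eps):
        return 1.0 / math.tanh(eps) - 1.0 / eps - target

    return brentq(f, 1e-6, 1e6)


def _sample_cos_theta(eps: float, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF sample of cos(theta) under P(c) ~ exp(eps*c) on [-1, 1]."""
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * eps)) / eps


def generate_wlc_ensemble(n_chains: int, n_segments: int, b: float,
                          lp: float, seed: int = 0) -> WLCEnsemble:
    """Generate discrete worm-like chains with persistence length ``lp``.

    Per-joint deflections are Boltzmann samples of the (1-cos) bending
    potential at the stiffness returned by :func:`discrete_bend_stiffness`,
    so the expected single-step tangent correlation is exactly exp(-b/lp)
    and the chain-level correlation decays as exp(-s/lp).
    """
    if n_chains < 1 or n_segments < 1:
        raise ConfigurationError("n_chains and n_segments must be >= 1")
    eps = discrete_bend_stiffness(lp, b)
    rng = np.random.default_rng(seed)

    tangents = np.zeros((n_chains, n_segments, 3))
    t = np.tile(np.array([1.0, 0.0, 0.0]), (n_chains, 1))
    tangents[:, 0] = t
    for k in range(1, n_segments):
        c = _sample_cos_theta(eps, rng.uniform(size=n_chains))
        s = np.sqrt(np.clip(1.0 - c * c, 0.0, None))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_chains)
        # orthonormal frame (t, n1, n2) around the previous tangent
        ref = np.where(np.abs(t[:, [0]]) < 0.9,
                       np.tile([1.0, 0.0, 0.0], (n_chains, 1)),
                       np.tile([0.0, 1.0, 0.0], (n_chains, 1)))
        n1 = np.cross(t, ref)
        n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
        n2 = np.cross(t, n1)
        t = (c[:, None] * t + s[:, None] *
             (np.cos(phi)[:, None] * n1 + np.sin(phi)[:, None] * n2))
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        tangents[:, k] = t

    chains = np.zeros((n_chains, n_segments + 1, 3))
    chains[:, 1:] = np.cumsum(b * tangents, axis=1)
    return WLCEnsemble(chains=chains, b=b, generating_lp=lp, seed=seed)


# -- analytic profile fixtures ----------------------------------------------

def make_gaussian_profile(sigma: float, amplitude: float = 1.0,
                          grid_step: float = 0.01,
                          z_range: float = 5.0) -> DensityProfile:
    """Symmetric Gaussian density profile sampled on a regular z grid."""
    if sigma <= 0 or grid_step <= 0:
        raise ConfigurationError("sigma and grid_step must be positive")
    n = int(round(z_range / grid_step))
    z = np.arange(-n, n + 1) * grid_step
    density = amplitude * np.exp(-0.5 * (z / sigma) ** 2)
    return DensityProfile(z=z, density=density, bin_width=grid_step)


# -- forward elasticity model ------------------------------------------------

def forward_orthotropic_stress(moduli: ElasticModuli, strain: float,
                               stretched_axis: str,
                               h_eff: float = 4.0) -> StressStrainRecord:
    """Noiseless clamped-strain stress response of an orthotropic sheet.

    With the transverse in-plane strain clamped at zero, the stress along
    the stretched axis is ``E_axis * eps / (1 - nu_gp*nu_pg)``; the
    transverse stress is the corresponding Poisson ratio times the axial
    stress (nu_pg when stretching along the glycan axis, nu_gp when
    stretching along the peptide axis).
    """
    axis_index(stretched_axis)
    prod = moduli.nu_gp * moduli.nu_pg
    if not (0 <= prod < 1):
        raise ValueError("non-physical Poisson ratio product")
    if stretched_axis == GLYCAN_AXIS:
        axial = moduli.E_g * strain / (1.0 - prod)
        trans = moduli.nu_pg * axial
        sigma_g, sigma_p = axial, trans
    else:
        axial = moduli.E_p * strain / (1.0 - prod)
        trans = moduli.nu_gp * axial
        sigma_g, sigma_p = trans, axial
    return StressStrainRecord(axis=stretched_axis, epsilon=strain,
                              sigma_g=sigma_g, sigma_p=sigma_p, h_eff=h_eff)
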