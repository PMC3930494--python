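"""Shared result containers: stress-strain records, elastic moduli, profiles.

These sit in their own module because both the synthetic forward models and
the measurement pipeline produce/consume them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GLYCAN_AXIS = "glycan"   # x, circumferential
PEPTIDE_AXIS = "peptide"  # y, axial

_AXIS_INDEX = {GLYCAN_AXIS: 0, PEPTIDE_AXIS: 1}


def axis_index(axis: str) -> int:
    """Map 'glycan'/'peptide' to the in-plane coordinate index (0=x, 1=y)."""
    try:
        return _AXIS_INDEX[axis]
    except KeyError:
        raise ValueError(f"axis must be 'glycan' or 'peptide', got {axis!r}")


@dataclass
class StressStrainRecord:
    """One clamped-strain measurement.

    The stretched in-plane axis carries strain ``epsilon``; the transverse
    in-plane axis is clamped at its relaxed length. Stresses are
    time-averaged and reported in MPa using the effective wall thickness
    ``h_eff`` for the cross-section.
    """
    axis: str                 # stretched axis: 'glycan' or 'peptide'
    epsilon: float            # applied engineering strain, dL/L
    sigma_g: float            # stress along the glycan (x) axis, MPa
    sigma_p: float            # stress along the peptide (y) axis, MPa
    h_eff: float = 4.0        # thickness used for the stress conversion, nm
    n_steps: int = 0
    seed: int | None = None
    short_averaging: bool = False  # warning flag: averaging window was small

    def __post_init__(self):
        axis_index(self.axis)
        if self.h_eff <= 0:
            raise ValueError("h_eff must be positive")
        if self.epsilon < 0:
            raise ValueError("strain must be non-negative")

    @property
    def sigma_axial(self) -> float:
        return self.sigma_g if self.axis == GLYCAN_AXIS else self.sigma_p

    @property
    def sigma_transverse(self) -> float:
        return self.sigma_p if self.axis == GLYCAN_AXIS else self.sigma_g


@dataclass
class ElasticModuli:
    """Orthotropic in-plane elastic constants of a wall patch.

    E_g / E_p are the Young's moduli along the glycan (circumferential) and
    peptide (axial) directions; nu_gp and nu_pg the corresponding Poisson
    ratios. ``symmetry_residual`` is |nu_gp/E_g - nu_pg/E_p|, zero for a
    self-consistent orthotropic material.
    """
    E_g: float                # MPa
    E_p: float                # MPa
    nu_gp: float
    nu_pg: float
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.E_g <= 0 or self.E_p <= 0:
            raise ValueError("Young's moduli must be positive")
        # stability bound; a (noise-induced) negative product is admissible
        prod = self.nu_gp * self.nu_pg
        if prod >= 1:
            raise ValueError(
                f"non-physical Poisson ratios: nu_gp*nu_pg = {prod:.4f}")

    @property
    def ratio(self) -> float:
        """Anisotropy ratio E_g/E_p from unrounded moduli."""
        return self.E_g / self.E_p

    @property
    def symmetry_residual(self) -> float:
        return abs(self.nu_gp / self.E_g - self.nu_pg / self.E_p)


@dataclass
class DensityProfile:
    """Mass density per slab along the wall normal (z)."""
    z: np.ndarray         # slab centers, nm
    density: np.ndarray   # Da/nm^3
    bin_width: float      # nm

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.z.shape != self.density.shape:
            raise ValueError("z grid and density must have equal length")


@dataclass
class PressureProfile:
    """In-plane stress resolved per slab along a chosen axis."""
    centers: np.ndarray   # slab centers, nm
    stress: np.ndarray    # MPa
    slab_width: float     # nm
    axis: int = 2         # coordinate index along which slabs are taken

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.centers.shape != self.stress.shape:
            raise ValueError("centers and stress must have equal length")
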