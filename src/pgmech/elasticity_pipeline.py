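"""From clamped-strain stress records to orthotropic elastic constants.

Under the clamped protocol (one in-plane dimension stretched, the other
held at its relaxed value) the axial stress grows linearly with strain
with slope E_axis/(1 - nu_gp*nu_pg), and the transverse stress is the
corresponding Poisson ratio times the axial stress. Fitting both slopes
through the origin for each stretch direction therefore yields:

    nu_pg = (transverse slope / axial slope) from glycan-stretch runs
    nu_gp = (transverse slope / axial slope) from peptide-stretch runs
    E_g   = (1 - nu_gp*nu_pg) * (glycan axial slope)
    E_p   = (1 - nu_gp*nu_pg) * (peptide axial slope)

The anisotropy ratio E_g/E_p is computed from the unrounded moduli.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .records import (ElasticModuli, StressStrainRecord, GLYCAN_AXIS,
                      PEPTIDE_AXIS)


class FitError(ValueError):
    """Raised when a stress-strain fit is degenerate or non-physical."""


def fit_stress_strain(records: list[StressStrainRecord],
                      axis: str) -> tuple[float, float]:
    """Origin-constrained least-squares slopes for one stretch direction.

    Returns ``(axial_slope, transverse_slope)`` in MPa per unit strain from
    the records whose stretched axis is ``axis``. Repeats at the same
    strain are pooled at the record level.
    """
    recs = [r for r in records if r.axis == axis]
    eps = np.array([r.epsilon for r in recs])
    if len(recs) < 1 or len(np.unique(eps[eps > 0])) < 1:
        raise FitError(f"need at least one non-zero strain for axis {axis!r}")
    if np.all(eps == eps[0]) and len(recs) > 1 and eps[0] == 0:
        raise FitError("all strains are zero")
    s_axial = np.array([r.sigma_axial for r in recs])
    s_trans = np.array([r.sigma_transverse for r in recs])
    denom = float(np.sum(eps * eps))
    if denom == 0:
        raise FitError("all strains are zero")
    axial_slope = float(np.sum(eps * s_axial) / denom)
    trans_slope = float(np.sum(eps * s_trans) / denom)
    return axial_slope, trans_slope


def estimate_moduli(glycan_fit: tuple[float, float],
                    peptide_fit: tuple[float, float]) -> ElasticModuli:
    """Orthotropic constants from the two per-axis slope pairs."""
    g_axial, g_trans = glycan_fit
    p_axial, p_trans = peptide_fit
    if g_axial <= 0 or p_axial <= 0:
        raise FitError("axial slopes must be positive")
    nu_pg = g_trans / g_axial
    nu_gp = p_trans / p_axial
    prod = nu_gp * nu_pg
    if prod >= 1:
        raise FitError(
            f"non-physical Poisson ratio product {prod:.3f} "
            f"(nu_gp={nu_gp:.3f}, nu_pg={nu_pg:.3f})")
    factor = 1.0 - prod
    return ElasticModuli(
        E_g=factor * g_axial, E_p=factor * p_axial,
        nu_gp=nu_gp, nu_pg=nu_pg,
        fit_diagnostics={"glycan_axial_slope": g_axial,
                         "glycan_transverse_slope": g_trans,
                         "peptide_axial_slope": p_axial,
                         "peptide_transverse_slope": p_trans})


def anisotropy_ratio(moduli: ElasticModuli) -> float:
    """E_g / E_p from unrounded moduli."""
    return moduli.ratio


def moduli_from_records(records: list[StressStrainRecord]) -> ElasticModuli:
    """Convenience: pooled fits for both axes, then the moduli estimate."""
    return estimate_moduli(fit_stress_strain(records, GLYCAN_AXIS),
                           fit_stress_strain(records, PEPTIDE_AXIS))


def run_elasticity_sweep(patch, params, glycan_strains=None,
                         peptide_strains=None, repeats: int = 2,
                         seed: int = 0, n_steps: int = 2000,
                         h_eff: float = 4.0):
    """Full clamped-strain protocol on a relaxed patch.

    For every strain on each axis (defaults: six glycan strains in
    1.25-17.5%, six peptide strains in 5-45%) and each repeat, the patch is
    affinely strained, equilibrated, and its time-averaged stresses
    recorded; the pooled records are fitted and the moduli estimated.
    Returns ``(moduli, records)``.
    """
    from .mechanics_engine import StrainSpec, apply_strain, measure_stress
    if glycan_strains is None:
        glycan_strains = np.linspace(0.0125, 0.175, 6)
    if peptide_strains is None:
        peptide_strains = np.linspace(0.05, 0.45, 6)
    records = []
    run = 0
    for axis, strains in ((GLYCAN_AXIS, glycan_strains),
                          (PEPTIDE_AXIS, peptide_strains)):
        for e in strains:
            for rep in range(repeats):
                strained = apply_strain(patch, StrainSpec(axis, float(e)))
                rec = measure_stress(strained, params, n_steps=n_steps,
                                     seed=seed + 7919 * run, h_eff=h_eff,
                                     axis=axis, epsilon=float(e))
                records.append(rec)
                run += 1
    return moduli_from_records(records), records


def records_to_frame(records: list[StressStrainRecord]) -> pd.DataFrame:
    """One row per record, for CSV export."""
    return pd.DataFrame([{
        "axis": r.axis, "strain": r.epsilon,
        "sigma_g_MPa": r.sigma_g, "sigma_p_MPa": r.sigma_p,
        "h_eff_nm": r.h_eff, "n_steps": r.n_steps, "seed": r.seed,
    } for r in records])


def moduli_summary_row(moduli: ElasticModuli, model: str = "custom") -> dict:
    """A Table-style summary row (2-decimal presentation rounding)."""
    return {
        "model": model,
        "nu_gp": round(moduli.nu_gp, 3),
        "nu_pg": round(moduli.nu_pg, 3),
        "E_g_MPa": round(moduli.E_g, 1),
        "E_p_MPa": round(moduli.E_p, 1),
        "ratio": round(moduli.ratio, 2),
        "symmetry_residual": moduli.symmetry_residual,
    }
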