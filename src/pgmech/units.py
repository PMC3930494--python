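"""Unit conventions and conversion constants.

Internal units: lengths in nm, energies in kBT (thermal energy at the
simulation temperature), masses in units of one GlcNAc bead (221 Da),
angles in degrees at API boundaries and radians internally.

Stress computed in kBT/nm^3 converts to MPa because 1 pN/nm^2 = 1 MPa.
"""

KB_PN_NM_PER_K = 0.0138064852  # Boltzmann constant, pN nm / K
DEFAULT_TEMPERATURE_K = 310.0

#: one GlcNAc bead, Da — mass scale of the reduced unit system
MASS_SCALE_DA = 221.0


def kbt_pn_nm(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy in pN nm at the given temperature."""
    return KB_PN_NM_PER_K * temperature_k


def stress_kbt_to_mpa(stress_kbt_per_nm3: float,
                      temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Convert a stress from kBT/nm^3 to MPa (1 pN/nm^2 == 1 MPa)."""
    return stress_kbt_per_nm3 * kbt_pn_nm(temperature_k)
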