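"""Physical constants and unit helpers shared across the package.

Energies are handled in eV, wavelengths in nm, doses in Gy, molar
absorptivities in M^-1 cm^-1, radiolytic yields (G-values) in mol/J.
"""

#: hc in eV·nm; converts photon wavelength (nm) to energy (eV) and back.
HC_EV_NM = 1239.841984

#: Boltzmann constant in eV/K (CODATA).
KB_EV_PER_K = 8.617333262e-5

#: display unit for radiolytic yields: 1e-7 mol/J.
G_DISPLAY_UNIT = 1e-7


def ev_to_nm(energy_ev: float) -> float:
    """Photon energy (eV) -> vacuum wavelength (nm)."""
    return HC_EV_NM / energy_ev


def nm_to_ev(wavelength_nm: float) -> float:
    """Vacuum wavelength (nm) -> photon energy (eV)."""
    return HC_EV_NM / wavelength_nm


def g_in_display_units(g_mol_per_j: float) -> float:
    """Express a yield stored in SI mol/J in the conventional 1e-7 mol/J unit."""
    return g_mol_per_j / G_DISPLAY_UNIT


def g_from_display_units(g_1e7: float) -> float:
    """Convert a yield quoted in 1e-7 mol/J units to SI mol/J."""
    return g_1e7 * G_DISPLAY_UNIT
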