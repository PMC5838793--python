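"""Physical constants and isotope abundances used across the package.

Two unit systems coexist deliberately: drift-tube plumbing (number density,
E/N, drift velocity) runs in SI-derived practical units (mbar, K, cm), while
capture-rate theory is evaluated in Gaussian/CGS units, as is conventional
for ion-molecule collision rate constants expressed in cm^3 s^-1.
"""

from __future__ import annotations

# --- SI side ---------------------------------------------------------------
KB_SI = 1.380649e-23  # Boltzmann constant, J/K (exact, 2019 SI)
MBAR_TO_PA = 100.0
TD = 1e-17  # one Townsend, V cm^2

#: Gas number density at 273.15 K and 1013.25 mbar (Loschmidt constant), cm^-3.
N0_CM3 = 1013.25 * MBAR_TO_PA / (KB_SI * 273.15) * 1e-6

#: Molar volume at the sccm reference state (273.15 K, 1013.25 mbar), cm^3/mol.
STANDARD_MOLAR_VOLUME_CM3 = 22414.0

# --- Gaussian/CGS side (capture-rate theory) -------------------------------
KB_CGS = 1.3807e-16       # erg/K
Q_ESU = 4.8032e-10        # elementary charge, e.s.u.
DA_TO_G = 1.66053907e-24  # atomic mass unit, g
A3_TO_CM3 = 1e-24         # polarizability volume, angstrom^3 -> cm^3
DEBYE_TO_ESU_CM = 1e-18   # dipole moment, Debye -> esu cm

# --- Isotope abundance ratios ----------------------------------------------
# Minor/major natural abundance ratios; the reciprocal of the per-atom ratio
# is the extrapolation factor from an isotopologue monitor channel back to
# the (possibly saturated) main channel.
R_18O_16O = 0.2005 / 99.757   # ~0.00201
R_15N_14N = 0.364 / 99.636    # ~0.00365
R_13C_12C = 1.07 / 98.93      # ~0.0108

#: Mean molar mass of the (humid) air buffer gas, Da.
BUFFER_MASS_DA = 28.8


def provenance_block() -> dict:
    """All physical constants and adopted abundances, for audit logging."""
    return {
        "kB_SI_J_per_K": KB_SI,
        "kB_CGS_erg_per_K": KB_CGS,
        "elementary_charge_esu": Q_ESU,
        "loschmidt_cm3": N0_CM3,
        "standard_molar_volume_cm3": STANDARD_MOLAR_VOLUME_CM3,
        "r_18O_16O": R_18O_16O,
        "r_15N_14N": R_15N_14N,
        "r_13C_12C": R_13C_12C,
        "buffer_mass_da": BUFFER_MASS_DA,
    }
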