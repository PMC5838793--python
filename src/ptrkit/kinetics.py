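"""Drift-tube physics and ion-molecule capture-rate kinetics.

The drift tube of a PTR-MS instrument is characterized by its reduced
electric field E/N (in Townsend), which sets the ion drift velocity, the
ion-molecule reaction time, and — through the Wannier relation — the
effective collision temperature governing capture rates.

Capture rate constants follow the parametrized-trajectory treatment: the
Langevin induced-dipole rate is scaled by a dimensionless factor K(x) that
depends on the reduced dipole parameter x of the neutral at the effective
temperature.  For apolar molecules (x = 0) the parametrization collapses to
the Langevin rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from . import constants as C

__all__ = [
    "DriftConditions",
    "MoleculeParams",
    "ReagentIon",
    "ReagentSpecies",
    "RateConstant",
    "number_density",
    "compute_EN",
    "calibrate_drift_length",
    "drift_velocity",
    "reaction_time",
    "effective_temperature",
    "langevin_rate",
    "su_parametrization_factor",
    "su_capture_rate",
    "HYDRONIUM",
    "HYDRONIUM_CLUSTER",
    "NITROSONIUM",
    "DIOXYGENYL",
    "REAGENT_IONS",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftConditions:
    """Drift-tube operating point.

    Parameters
    ----------
    voltage : float
        Drift voltage U, V.
    pressure : float
        Drift-tube pressure p, mbar.
    temperature : float
        Drift-tube temperature T, K.
    drift_length : float
        Drift-tube length d, cm.  Default 9.6 cm, calibrated so that 600 V
        at 2.30 mbar / 383.15 K yields 144 Td.
    reduced_mobility : float
        Reduced ion mobility mu_0 of the reagent ion in the buffer gas,
        cm^2 V^-1 s^-1.
    """

    voltage: float
    pressure: float
    temperature: float
    drift_length: float = 9.6
    reduced_mobility: float = 2.76

    def __post_init__(self) -> None:
        for name in ("voltage", "pressure", "temperature", "drift_length",
                     "reduced_mobility"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DriftConditions.{name} must be > 0")


@dataclass(frozen=True)
class MoleculeParams:
    """Neutral-molecule parameters entering the capture-rate calculation."""

    name: str
    formula: str
    molar_mass: float       # Da
    polarizability: float   # angstrom^3
    dipole_moment: float    # Debye

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")
        if self.polarizability < 0 or self.dipole_moment < 0:
            raise ValueError("polarizability and dipole_moment must be >= 0")


class ReagentSpecies(str, Enum):
    HYDRONIUM = "hydronium"
    HYDRONIUM_WATER_CLUSTER = "hydronium_water_cluster"
    NITROSONIUM = "nitrosonium"
    DIOXYGENYL = "dioxygenyl"


@dataclass(frozen=True)
class ReagentIon:
    """A reagent (primary) ion and its saturation-workaround bookkeeping.

    ``monitor_mz`` is the minor-isotopologue channel used to back out the
    saturated main-channel intensity; ``isotope_factor`` is the
    natural-abundance multiplier monitor -> main.
    """

    species: ReagentSpecies
    ion_mass: float        # Da
    main_mz: float         # Th, the (saturating) main channel
    monitor_mz: float      # Th, isotopologue monitor channel
    isotope_factor: float  # main/monitor abundance ratio, > 1
    reduced_mobility: float = 2.8  # cm^2 V^-1 s^-1 in air

    def __post_init__(self) -> None:
        if self.isotope_factor <= 1:
            raise ValueError("isotope_factor must exceed 1")
        if self.monitor_mz <= 0:
            raise ValueError("monitor_mz must be > 0")


class RateMethod(str, Enum):
    LANGEVIN = "langevin"
    SU_PARAMETRIZED = "su_parametrized"


@dataclass(frozen=True)
class RateConstant:
    """A capture rate constant with the conditions it was evaluated at."""

    value: float                 # cm^3 s^-1
    effective_temperature: float  # K
    method: RateMethod = RateMethod.SU_PARAMETRIZED

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("rate constant must be > 0")


# Preset reagent ions.  H3O+ monitored through the single-18O isotopologue
# at 21.02 Th; its water cluster through 39.03 Th (two oxygens, so twice the
# per-atom ratio); NO+ through the 15N channel at 30.99 Th; O2+ through the
# 16O18O channel at 33.99 Th (two oxygens).
HYDRONIUM = ReagentIon(ReagentSpecies.HYDRONIUM, 19.018, 19.02, 21.02,
                       1.0 / C.R_18O_16O, reduced_mobility=2.76)
HYDRONIUM_CLUSTER = ReagentIon(ReagentSpecies.HYDRONIUM_WATER_CLUSTER,
                               37.028, 37.03, 39.03, 1.0 / (2 * C.R_18O_16O),
                               reduced_mobility=2.76)
NITROSONIUM = ReagentIon(ReagentSpecies.NITROSONIUM, 29.998, 30.00, 30.99,
                         1.0 / C.R_15N_14N)
DIOXYGENYL = ReagentIon(ReagentSpecies.DIOXYGENYL, 31.990, 31.99, 33.99,
                        1.0 / (2 * C.R_18O_16O))

REAGENT_IONS: dict[str, ReagentIon] = {
    "hydronium": HYDRONIUM,
    "hydronium_water_cluster": HYDRONIUM_CLUSTER,
    "nitrosonium": NITROSONIUM,
    "dioxygenyl": DIOXYGENYL,
}


# --------------------------------------------------------------------------
# drift-tube plumbing
# --------------------------------------------------------------------------

def number_density(pressure: float, temperature: float) -> float:
    """Ideal-gas number density N = p / (kB T), cm^-3.

    Parameters are in mbar and kelvin.
    """
    if pressure <= 0 or temperature <= 0:
        raise ValueError("pressure and temperature must be > 0")
    return pressure * C.MBAR_TO_PA / (C.KB_SI * temperature) * 1e-6


def compute_EN(conditions: DriftConditions) -> float:
    """Reduced electric field E/N in Townsend (unrounded).

    E/N = (U/d) / N; linear in voltage at fixed pressure and temperature.
    Round to the nearest integer to match conventional Td labels.
    """
    n = number_density(conditions.pressure, conditions.temperature)
    field = conditions.voltage / conditions.drift_length  # V/cm
    return field / n / C.TD


def calibrate_drift_length(voltage: float, pressure: float,
                           temperature: float, target_td: float) -> float:
    """Drift length (cm) that makes the given operating point hit target_td."""
    if target_td <= 0:
        raise ValueError("target_td must be > 0")
    n = number_density(pressure, temperature)
    return voltage / (target_td * C.TD * n)


def drift_velocity(conditions: DriftConditions) -> float:
    """Ion drift velocity v_d = mu_0 N_0 (E/N), cm/s."""
    en = compute_EN(conditions)
    return conditions.reduced_mobility * C.N0_CM3 * en * C.TD


def reaction_time(conditions: DriftConditions) -> float:
    """Ion residence (reaction) time t = d / v_d, seconds."""
    v = drift_velocity(conditions)
    if v <= 0:
        raise ValueError("drift velocity must be > 0")
    return conditions.drift_length / v


def effective_temperature(conditions: DriftConditions, ion_mass: float,
                          buffer_mass: float = C.BUFFER_MASS_DA,
                          neutral_mass: float | None = None) -> float:
    """Wannier effective temperature of ion-neutral collisions, K.

    The mean ion kinetic energy in the drift field is
    ``KE_ion = (3/2) kB T + (1/2)(m_i + m_b) v_d^2`` (thermal plus field
    heating shared with the buffer); the center-of-mass collision energy
    with a neutral of mass M_R replaces the superthermal part by its
    reduced-frame share, and T_eff is the temperature with that mean energy.
    With no neutral mass given the ion kinetic-energy temperature is
    returned.  At zero field this is exactly the gas temperature.
    """
    if ion_mass <= 0 or buffer_mass <= 0:
        raise ValueError("masses must be > 0")
    if neutral_mass is not None and neutral_mass <= 0:
        raise ValueError("masses must be > 0")
    v = drift_velocity(conditions)  # cm/s
    thermal = 1.5 * C.KB_CGS * conditions.temperature  # erg
    m_sum_g = (ion_mass + buffer_mass) * C.DA_TO_G
    ke_ion = thermal + 0.5 * m_sum_g * v * v
    if neutral_mass is None:
        ke_cm = ke_ion
    else:
        share = neutral_mass / (ion_mass + neutral_mass)
        ke_cm = thermal + share * (ke_ion - thermal)
    return ke_cm / (1.5 * C.KB_CGS)


# --------------------------------------------------------------------------
# capture rates
# --------------------------------------------------------------------------

def langevin_rate(polarizability: float, reduced_mass: float) -> float:
    """Langevin capture rate k_L = 2 pi q sqrt(alpha / mu), cm^3 s^-1.

    ``polarizability`` in angstrom^3, ``reduced_mass`` in Da; evaluated in
    Gaussian units.  Temperature-independent.
    """
    if polarizability <= 0 or reduced_mass <= 0:
        raise ValueError("polarizability and reduced_mass must be > 0")
    alpha_cm3 = polarizability * C.A3_TO_CM3
    mu_g = reduced_mass * C.DA_TO_G
    return 2.0 * math.pi * C.Q_ESU * math.sqrt(alpha_cm3 / mu_g)


def su_parametrization_factor(x: float) -> float:
    """Trajectory-parametrization enhancement K(x) over the Langevin rate.

    K(x) = (x + 0.5090)^2 / 10.526 + 0.9754   for x < 2
    K(x) = 0.4767 x + 0.6200                  for x >= 2

    Continuous at x = 2 (both branches give 1.5734); K(0) = 1 to within
    3e-5, recovering the Langevin limit for apolar neutrals.
    """
    if x < 0:
        raise ValueError("reduced dipole parameter x must be >= 0")
    if x < 2.0:
        return (x + 0.5090) ** 2 / 10.526 + 0.9754
    return 0.4767 * x + 0.6200


def su_capture_rate(params: MoleculeParams, ion_mass: float,
                    t_eff: float) -> RateConstant:
    """Parametrized-trajectory capture rate of an ion with a polar neutral.

    The reduced dipole parameter is
    ``x = mu_D / sqrt(2 alpha kB T_eff)`` (Gaussian units), and
    ``k = K(x) k_L`` with the reduced mass of the ion-neutral pair.
    """
    if t_eff <= 0:
        raise ValueError("t_eff must be > 0")
    if ion_mass <= 0:
        raise ValueError("ion_mass must be > 0")
    if params.polarizability == 0 and params.dipole_moment > 0:
        raise ValueError(
            "reduced dipole parameter undefined for a polar molecule with "
            "zero polarizability")
    mu_da = ion_mass * params.molar_mass / (ion_mass + params.molar_mass)
    k_l = langevin_rate(params.polarizability, mu_da)
    if params.dipole_moment == 0:
        x = 0.0
    else:
        alpha_cm3 = params.polarizability * C.A3_TO_CM3
        x = (params.dipole_moment * C.DEBYE_TO_ESU_CM
             / math.sqrt(2.0 * alpha_cm3 * C.KB_CGS * t_eff))
    return RateConstant(value=su_parametrization_factor(x) * k_l,
                        effective_temperature=t_eff)
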