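"""Concentration, sensitivity, and optimal-condition selection.

The standard pseudo-first-order quantitation relation converts product-ion
count rates into an analyte number density,

    n_A = sum(I_products) / (t * sum_r k_r I_r),

where t is the ion reaction time in the drift tube and the denominator sums
over the reactive reagent-ion populations: the bare primary ion always, and
the hydronium-water cluster as a second reactive species when it carries an
appreciable share of the reagent current (low E/N operation).  Mixing
ratios follow by dividing by the buffer-gas number density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragmentation import BranchingTable
from .ion_corrections import PrimaryIonSignal
from .kinetics import (DriftConditions, RateConstant, ReagentSpecies,
                       number_density, reaction_time)
from .peaktable import PeakTable

__all__ = ["ConcentrationResult", "SensitivityProfile", "concentration",
           "sensitivity", "optimal_conditions"]


@dataclass(frozen=True)
class ConcentrationResult:
    """A mixing-ratio estimate with every input recorded for audit."""

    compound: str
    reagent_label: str
    mixing_ratio_ppbv: float
    product_cps_sum: float   # transmission-corrected
    primary_cps: float       # isotopologue-extrapolated
    cluster_cps: float
    rate_primary: float      # cm^3 s^-1
    rate_cluster: float | None
    reaction_time_s: float

    def __post_init__(self) -> None:
        if self.mixing_ratio_ppbv < 0:
            raise ValueError("mixing ratio must be >= 0")


def concentration(products_cps: float | np.ndarray,
                  primary: PrimaryIonSignal,
                  rate: RateConstant,
                  conditions: DriftConditions,
                  cluster_rate: RateConstant | None = None,
                  compound: str = "") -> ConcentrationResult:
    """Analyte mixing ratio from transmission-corrected product signals.

    ``products_cps`` is the corrected count-rate sum over all attributed
    product channels (an array is summed).  In hydronium mode with a
    nonzero cluster signal, ``cluster_rate`` (the analyte's capture rate
    with the water cluster) is required and the cluster population enters
    the denominator additively.
    """
    products = float(np.sum(products_cps))
    if products < 0:
        raise ValueError("product count rates must be >= 0")
    if primary.extrapolated_cps <= 0:
        raise ValueError("zero primary-ion signal")
    t = reaction_time(conditions)
    denom = rate.value * primary.extrapolated_cps
    k37 = None
    if primary.cluster_cps > 0:
        if primary.reagent.species is ReagentSpecies.HYDRONIUM:
            if cluster_rate is None:
                raise ValueError(
                    "cluster signal present but no cluster rate constant "
                    "supplied")
            denom += cluster_rate.value * primary.cluster_cps
            k37 = cluster_rate.value
        # NO+ water clusters stay below the reactivity threshold and are
        # deliberately not part of the denominator
    n_a = products / (t * denom)  # cm^-3
    n_gas = number_density(conditions.pressure, conditions.temperature)
    return ConcentrationResult(
        compound=compound, reagent_label=primary.reagent.species.value,
        mixing_ratio_ppbv=n_a / n_gas * 1e9,
        product_cps_sum=products,
        primary_cps=primary.extrapolated_cps,
        cluster_cps=primary.cluster_cps,
        rate_primary=rate.value, rate_cluster=k37, reaction_time_s=t)


@dataclass
class SensitivityProfile:
    """Counts-per-ppbV of a reference channel across the E/N grid."""

    compound: str
    reagent_label: str
    reference_mz: float
    points: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    # index: integer Td; values: cps/ppbV

    def add(self, td: int, value: float) -> None:
        if value < 0:
            raise ValueError("sensitivity must be >= 0")
        self.points.loc[int(td)] = value
        self.points = self.points.sort_index(ascending=False)


def sensitivity(table: PeakTable, result: ConcentrationResult,
                reference_mz: float,
                mask: np.ndarray | None = None) -> float:
    """Raw (uncorrected) reference-channel cps per ppbV of analyte.

    The concentration in the denominator accounts for all product ions;
    the numerator is the as-recorded rate of the single reference peak, so
    the figure reflects what the instrument actually delivers per unit of
    analyte under those conditions.
    """
    if result.mixing_ratio_ppbv <= 0:
        raise ValueError("zero concentration: sensitivity undefined")
    trace = table.trace(reference_mz)
    if mask is not None:
        trace = trace[mask]
    return float(np.mean(trace)) / result.mixing_ratio_ppbv


def optimal_conditions(profile: SensitivityProfile, branching: BranchingTable,
                       purity_floor: float = 0.75,
                       diagnostic_mz: float | None = None) -> int:
    """Recommended E/N: best sensitivity among sufficiently pure plateaus.

    A plateau qualifies when the diagnostic ion (default: the profile's
    reference channel) carries at least ``purity_floor`` of the product
    signal; among qualifying plateaus the most sensitive wins, with ties
    broken toward lower Td (gentler conditions).  If no plateau meets the
    floor, the best-available plateau is returned with a warning.
    """
    mz = profile.reference_mz if diagnostic_mz is None else diagnostic_mz
    idx = branching.data.index.to_numpy(dtype=float)
    hit = np.flatnonzero(np.abs(idx - mz) <= 0.005)
    if hit.size != 1:
        raise KeyError(f"diagnostic channel {mz:.2f} not in branching table")
    shares = branching.data.iloc[hit[0]] / 100.0
    common = [td for td in profile.points.index if td in shares.index]
    if not common:
        raise ValueError("profile and branching table share no E/N steps")
    qualifying = [td for td in common
                  if float(shares[td] if pd.notna(shares[td]) else 0.0)
                  >= purity_floor]
    pool = qualifying
    if not pool:
        warnings.warn("no E/N step meets the purity floor; returning the "
                      "best-available step", stacklevel=2)
        pool = common
    # max sensitivity, ties toward lower Td
    best = min(pool, key=lambda td: (-profile.points[td], td))
    return int(best)
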