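"""End-to-end analysis chains composing the individual stages.

These functions are the library form of the command-line workflow: take a
raw peak table, apply transmission correction and primary-ion
extrapolation, and produce branching tables, concentrations, sensitivity
profiles, or diffusion rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragmentation import (BranchingTable, RampSchedule, attribute_products,
                            branching_ratios, segment_ramp)
from .gravimetric import spectrometric_rate
from .ion_corrections import extrapolate_primary
from .kinetics import (REAGENT_IONS, MoleculeParams, ReagentSpecies,
                       compute_EN)
from .peaktable import PeakTable, TransmissionCurve, correct_transmission
from .quantify import (ConcentrationResult, SensitivityProfile, concentration,
                       sensitivity)
from .synthetic import analyte_rates, reagent_blocks

__all__ = ["analyze_ramp_run", "sensitivity_profile",
           "recover_diffusion_rates", "RampAnalysis"]


@dataclass
class RampAnalysis:
    products: list[float]
    branching: BranchingTable
    slices: list[PeakTable]


def analyze_ramp_run(table: PeakTable, schedule: RampSchedule,
                     curve: TransmissionCurve, compound: str = "",
                     **attr_kwargs) -> RampAnalysis:
    """Attribute products of a spike + ramp run and tabulate branching."""
    corrected = (table if table.transmission_corrected
                 else correct_transmission(table, curve))
    products = attribute_products(corrected, schedule.spike_time,
                                  **attr_kwargs)
    slices = segment_ramp(corrected, schedule)
    branching = branching_ratios(slices, products, compound=compound)
    return RampAnalysis(products=products, branching=branching,
                        slices=slices)


def _step_concentration(corr_slice: PeakTable, products: list[float],
                        compound: MoleculeParams, reagent_label: str,
                        k_override: float | None = None
                        ) -> ConcentrationResult:
    reagent = REAGENT_IONS[reagent_label]
    cond = corr_slice.conditions(voltage=float(corr_slice.voltages[0]))
    signal = extrapolate_primary(corr_slice, reagent)
    k_p, k_c = analyte_rates(compound, reagent, cond, k_override)
    prod_sum = sum(float(np.mean(corr_slice.trace(mz))) for mz in products)
    cluster_rate = (k_c if reagent.species is ReagentSpecies.HYDRONIUM
                    else None)
    return concentration(prod_sum, signal, k_p, cond,
                         cluster_rate=cluster_rate, compound=compound.name)


def sensitivity_profile(table: PeakTable, schedule: RampSchedule,
                        curve: TransmissionCurve, compound: MoleculeParams,
                        products: list[float], reference_mz: float,
                        k_override: float | None = None
                        ) -> SensitivityProfile:
    """Per-E/N sensitivity of a reference channel from a ramp run.

    Concentration at each plateau is computed from all product ions on the
    transmission-corrected table; the numerator is the raw (uncorrected)
    reference-channel rate, as sensitivities are conventionally quoted.
    """
    raw_slices = segment_ramp(table, schedule)
    corrected = correct_transmission(table, curve)
    corr_slices = segment_ramp(corrected, schedule)
    profile = SensitivityProfile(compound=compound.name,
                                 reagent_label=table.reagent_label,
                                 reference_mz=reference_mz)
    for raw_sl, corr_sl in zip(raw_slices, corr_slices):
        cond = corr_sl.conditions(voltage=float(corr_sl.voltages[0]))
        td = int(round(compute_EN(cond)))
        result = _step_concentration(corr_sl, products, compound,
                                     table.reagent_label, k_override)
        profile.add(td, sensitivity(raw_sl, result, reference_mz))
    return profile


def recover_diffusion_rates(table: PeakTable, compound: MoleculeParams,
                            products_by_reagent: dict[str, list[float]],
                            curve: TransmissionCurve, flow_sccm: float,
                            k_overrides: dict[str, float] | None = None
                            ) -> pd.DataFrame:
    """Spectrometric release rates from a cycling diffusion-tube run.

    Returns one row per reagent-ion block with the recovered mixing ratio
    (ppbV) and release rate (ng/min).
    """
    k_overrides = k_overrides or {}
    corrected = (table if table.transmission_corrected
                 else correct_transmission(table, curve))
    rows = []
    for label, block in reagent_blocks(corrected):
        products = products_by_reagent[label]
        result = _step_concentration(block, products, compound, label,
                                     k_overrides.get(label))
        rate = spectrometric_rate(result.mixing_ratio_ppbv, flow_sccm,
                                  compound.molar_mass)
        rows.append({"reagent": label,
                     "mixing_ratio_ppbv": result.mixing_ratio_ppbv,
                     "rate_ng_min": rate,
                     "product_cps": result.product_cps_sum,
                     "primary_cps": result.primary_cps,
                     "cluster_cps": result.cluster_cps})
    return pd.DataFrame(rows)
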