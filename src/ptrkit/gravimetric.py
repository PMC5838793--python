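"""Diffusion-tube gravimetric calibration and accuracy statistics.

A diffusion tube releases a compound at a steady rate; weighing it before
and after a run gives a gravimetric release rate that serves as the
reference against which spectrometric quantitation is judged.  The
spectrometric release rate follows from the measured mixing ratio, the
oven carrier-gas flow and the compound's molar mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C

__all__ = ["DiffusionRecord", "AccuracyRow", "gravimetric_rate",
           "spectrometric_rate", "error_pct", "cv_pct", "accuracy_table",
           "read_diffusion_records", "mixing_ratio_from_rate"]


@dataclass(frozen=True)
class DiffusionRecord:
    """One gravimetric measurement of a diffusion tube."""

    compound: str
    molar_mass: float       # Da
    oven_flow: float        # sccm
    oven_temperature: float  # K
    weight_loss: float      # mg
    duration: float         # min
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        if self.weight_loss < 0:
            raise ValueError("weight_loss must be >= 0")
        if self.duration <= 0 or self.oven_flow <= 0:
            raise ValueError("duration and oven_flow must be > 0")


@dataclass(frozen=True)
class AccuracyRow:
    compound: str
    reagent_label: str
    gravimetric_mean: float  # ng/min
    gravimetric_sd: float
    ptr_mean: float          # ng/min
    ptr_sd: float
    error_pct: float

    def __post_init__(self) -> None:
        if self.gravimetric_mean <= 0 or self.ptr_mean <= 0:
            raise ValueError("rates must be > 0")
        if self.gravimetric_sd < 0 or self.ptr_sd < 0:
            raise ValueError("SDs must be >= 0")


def gravimetric_rate(record: DiffusionRecord) -> float:
    """Release rate from weight loss, ng/min."""
    return record.weight_loss * 1e6 / record.duration


def spectrometric_rate(mixing_ratio_ppbv: float, flow_sccm: float,
                       molar_mass: float,
                       molar_volume_cm3: float = C.STANDARD_MOLAR_VOLUME_CM3
                       ) -> float:
    """Release rate implied by a measured mixing ratio, ng/min.

    ``rate = x * flow / V_m * M`` with x the mixing ratio (mole fraction),
    flow in standard cm^3/min and V_m the molar volume at the sccm
    reference state (273.15 K, 1013.25 mbar by default).
    """
    if mixing_ratio_ppbv < 0:
        raise ValueError("mixing ratio must be >= 0")
    if flow_sccm <= 0 or molar_mass <= 0 or molar_volume_cm3 <= 0:
        raise ValueError("flow, molar mass and molar volume must be > 0")
    mol_per_min = mixing_ratio_ppbv * 1e-9 * flow_sccm / molar_volume_cm3
    return mol_per_min * molar_mass * 1e9  # g -> ng


def mixing_ratio_from_rate(rate_ng_min: float, flow_sccm: float,
                           molar_mass: float,
                           molar_volume_cm3: float =
                           C.STANDARD_MOLAR_VOLUME_CM3) -> float:
    """Inverse of :func:`spectrometric_rate`: steady mixing ratio, ppbV."""
    return rate_ng_min * molar_volume_cm3 / (flow_sccm * molar_mass)


def error_pct(gravimetric: float, spectrometric: float) -> float:
    """Relative quantitation error vs the gravimetric reference, percent.

    Sign convention: positive when the spectrometric estimate falls short
    of the gravimetric reference, ``100 (g - s) / g``, reported to one
    decimal.  Not antisymmetric under swapping arguments (the denominator
    changes).
    """
    if gravimetric <= 0:
        raise ValueError("gravimetric reference must be > 0")
    return round(100.0 * (gravimetric - spectrometric) / gravimetric, 1)


def cv_pct(replicate_rates) -> float:
    """Coefficient of variation (sample SD over mean), percent."""
    rates = np.asarray(replicate_rates, dtype=float)
    if rates.size < 2:
        raise ValueError("need at least 2 replicates for a CV")
    mean = rates.mean()
    if mean == 0:
        raise ValueError("zero mean rate")
    return float(100.0 * rates.std(ddof=1) / mean)


def accuracy_table(rows: list[AccuracyRow]) -> pd.DataFrame:
    """Accuracy report: one row per compound x reagent ion."""
    return pd.DataFrame(
        [{"compound": r.compound, "reagent": r.reagent_label,
          "gravimetric_ng_min": r.gravimetric_mean,
          "gravimetric_sd": r.gravimetric_sd,
          "ptr_ng_min": r.ptr_mean, "ptr_sd": r.ptr_sd,
          "error_pct": r.error_pct} for r in rows])


def read_diffusion_records(path) -> list[DiffusionRecord]:
    """Load diffusion records from the input CSV dialect.

    Columns: compound, molar_mass_da, flow_sccm, temp_C, weight_loss_mg,
    duration_min, replicate.
    """
    df = pd.read_csv(path, comment="#")
    required = {"compound", "molar_mass_da", "flow_sccm", "temp_C",
                "weight_loss_mg", "duration_min", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"diffusion CSV missing columns: {sorted(missing)}")
    return [DiffusionRecord(compound=row.compound,
                            molar_mass=float(row.molar_mass_da),
                            oven_flow=float(row.flow_sccm),
                            oven_temperature=float(row.temp_C) + 273.15,
                            weight_loss=float(row.weight_loss_mg),
                            duration=float(row.duration_min),
                            replicate_id=str(row.replicate))
            for row in df.itertuples()]
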