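"""Compound library: molecular parameters and product-channel catalogs.

The bundled CSV covers the thirteen study compounds (linear aldehydes
C4-C10, short-chain fatty acids, phenols) and the aromatic reference mix
used for the transmission curve.  Users supply the same format for their
own compounds; per-reagent rate-constant overrides can be attached when
measured values are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .kinetics import MoleculeParams

__all__ = ["CompoundEntry", "load_compound_library",
           "load_reference_rates", "TRANSMISSION_REFERENCE_COMPOUNDS"]

#: Aromatic reference-mix members used to fit the transmission curve.
TRANSMISSION_REFERENCE_COMPOUNDS = (
    "benzene", "toluene", "styrene", "ethylbenzene", "chlorobenzene",
    "1-2-4-trimethylbenzene", "1-3-dichlorobenzene",
    "1-2-4-trichlorobenzene")


@dataclass(frozen=True)
class CompoundEntry:
    params: MoleculeParams
    product_channels: dict[str, tuple[float, ...]] = field(
        default_factory=dict)  # reagent label -> candidate product m/z
    k_overrides: dict[str, float] = field(default_factory=dict)
    # reagent label -> measured rate constant, cm^3/s

    @property
    def name(self) -> str:
        return self.params.name


def _parse_channels(cell) -> tuple[float, ...]:
    if not isinstance(cell, str) or not cell.strip():
        return ()
    return tuple(float(x) for x in cell.split(";"))


def load_compound_library(path: str | Path | None = None
                          ) -> dict[str, CompoundEntry]:
    """Load a compound library CSV (default: the bundled one)."""
    if path is None:
        path = resources.files("ptrkit.data") / "compound_library.csv"
    df = pd.read_csv(path, comment="#")
    out: dict[str, CompoundEntry] = {}
    for row in df.itertuples():
        params = MoleculeParams(name=row.name, formula=row.formula,
                                molar_mass=float(row.molar_mass_da),
                                polarizability=float(row.polarizability_A3),
                                dipole_moment=float(row.dipole_D))
        channels = {
            "hydronium": _parse_channels(row.products_hydronium),
            "nitrosonium": _parse_channels(row.products_nitrosonium),
            "dioxygenyl": _parse_channels(row.products_dioxygenyl),
        }
        out[params.name] = CompoundEntry(params=params,
                                         product_channels=channels)
    return out


def load_reference_rates(path: str | Path | None = None) -> pd.DataFrame:
    """Published gravimetric/spectrometric diffusion-rate validation set."""
    if path is None:
        path = resources.files("ptrkit.data") / "reference_diffusion_rates.csv"
    return pd.read_csv(path, comment="#")
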