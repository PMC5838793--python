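"""Primary-ion extrapolation, 13C deconvolution, and daily QC checks.

Main reagent-ion channels saturate the detector, so their intensities are
recovered from minor-isotopologue monitor channels scaled by natural
abundance.  Product peaks one mass unit above a molecular ion can mix the
13C isotopologue with a genuine protonated ion; subtracting the expected
13C contribution isolates the latter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from . import constants as C
from .kinetics import (DIOXYGENYL, HYDRONIUM, HYDRONIUM_CLUSTER, NITROSONIUM,
                       ReagentIon, ReagentSpecies)
from .peaktable import PeakTable

__all__ = ["PrimaryIonSignal", "C13Correction", "QCCheck", "QCReport",
           "extrapolate_primary", "cluster_fraction", "c13_deconvolve",
           "qc_impurities", "qc_ratio_stability", "format_qc_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrimaryIonSignal:
    """Reagent-ion beam intensity recovered from its isotopologue monitor."""

    reagent: ReagentIon
    direct_cps: float        # main channel as recorded (possibly saturated)
    monitor_cps: float       # isotopologue monitor channel
    extrapolated_cps: float  # monitor * isotope factor
    cluster_cps: float = 0.0  # hydronium-water cluster (hydronium mode)

    def __post_init__(self) -> None:
        for name in ("direct_cps", "monitor_cps", "extrapolated_cps",
                     "cluster_cps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def extrapolate_primary(table: PeakTable, reagent: ReagentIon,
                        mask: np.ndarray | None = None) -> PrimaryIonSignal:
    """Recover the primary-ion intensity from the isotopologue monitor.

    ``mask`` restricts the time bins averaged (default: all bins).  In
    hydronium mode the water-cluster signal is likewise extrapolated from
    its 18O monitor at 39.03 Th when that channel is present.
    """
    if mask is None:
        mask = np.ones(table.times.size, dtype=bool)
    try:
        monitor = float(np.mean(table.trace(reagent.monitor_mz)[mask]))
    except KeyError:
        raise KeyError(
            f"monitor channel {reagent.monitor_mz:.2f} Th missing from table")
    try:
        direct = float(np.mean(table.trace(reagent.main_mz)[mask]))
    except KeyError:
        direct = 0.0
    cluster = 0.0
    if reagent.species is ReagentSpecies.HYDRONIUM:
        try:
            cluster_monitor = float(
                np.mean(table.trace(HYDRONIUM_CLUSTER.monitor_mz)[mask]))
            cluster = cluster_monitor * HYDRONIUM_CLUSTER.isotope_factor
        except KeyError:
            cluster = 0.0
    return PrimaryIonSignal(reagent=reagent, direct_cps=direct,
                            monitor_cps=monitor,
                            extrapolated_cps=monitor * reagent.isotope_factor,
                            cluster_cps=cluster)


def cluster_fraction(signal: PrimaryIonSignal) -> float:
    """Fraction of reagent-ion current carried by the water cluster."""
    total = signal.extrapolated_cps + signal.cluster_cps
    if total <= 0:
        raise ValueError("zero total primary-ion signal")
    return signal.cluster_cps / total


class C13Correction(NamedTuple):
    corrected_cps: float
    expected_c13_cps: float
    overlap_detected: bool  # M+1 exceeds the pure-13C expectation


def c13_deconvolve(m_counts: float, mplus1_counts: float, carbon_count: int,
                   r13: float = C.R_13C_12C) -> C13Correction:
    """Remove the 13C isotopologue share from an M+1 peak.

    The expected 13C contribution is ``m_counts * carbon_count * r13``;
    the remainder (clamped at zero) is attributed to a coincident product
    ion (e.g. a protonated molecule overlapping the isotopologue).
    """
    if carbon_count < 1:
        raise ValueError("carbon_count must be >= 1")
    if m_counts < 0 or mplus1_counts < 0:
        raise ValueError("counts must be >= 0")
    expected = m_counts * carbon_count * r13
    residual = mplus1_counts - expected
    if residual < 0:
        warnings.warn("M+1 below the 13C expectation; clamping to zero",
                      stacklevel=2)
        residual = 0.0
    return C13Correction(corrected_cps=residual, expected_c13_cps=expected,
                         overlap_detected=mplus1_counts > expected)


# --------------------------------------------------------------------------
# quality control
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QCCheck:
    name: str
    value: float
    threshold: float
    passed: bool


@dataclass(frozen=True)
class QCReport:
    checks: tuple[QCCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)


#: Tolerated impurity-ion fractions of the total reagent current per mode.
IMPURITY_THRESHOLDS = {
    ReagentSpecies.HYDRONIUM: {"dioxygenyl": 0.02},
    ReagentSpecies.NITROSONIUM: {"nitronium": 0.03},
    ReagentSpecies.DIOXYGENYL: {"nitrosonium+nitronium": 0.05},
}

_NITRONIUM_MZ = 45.99  # NO2+


def qc_impurities(table: PeakTable, reagent: ReagentIon) -> QCReport:
    """Check impurity-ion fractions against the per-mode tolerances.

    Fractions are impurity cps over total primary cps (isotopologue-
    extrapolated main beam plus the impurity itself).  Missing impurity
    channels count as zero signal.
    """
    signal = extrapolate_primary(table, reagent)
    primary_total = signal.extrapolated_cps + signal.cluster_cps

    def channel_mean(mz: float) -> float:
        try:
            return float(np.mean(table.trace(mz)))
        except KeyError:
            return 0.0

    checks: list[QCCheck] = []
    if reagent.species is ReagentSpecies.HYDRONIUM:
        imp = channel_mean(DIOXYGENYL.main_mz)
        frac = imp / (primary_total + imp) if primary_total + imp > 0 else 0.0
        thr = IMPURITY_THRESHOLDS[reagent.species]["dioxygenyl"]
        checks.append(QCCheck("O2+ fraction in hydronium mode", frac, thr,
                              frac < thr))
    elif reagent.species is ReagentSpecies.NITROSONIUM:
        imp = channel_mean(_NITRONIUM_MZ)
        frac = imp / (primary_total + imp) if primary_total + imp > 0 else 0.0
        thr = IMPURITY_THRESHOLDS[reagent.species]["nitronium"]
        checks.append(QCCheck("NO2+ fraction in nitrosonium mode", frac, thr,
                              frac < thr))
    elif reagent.species is ReagentSpecies.DIOXYGENYL:
        imp = channel_mean(NITROSONIUM.main_mz) + channel_mean(_NITRONIUM_MZ)
        frac = imp / (primary_total + imp) if primary_total + imp > 0 else 0.0
        thr = IMPURITY_THRESHOLDS[reagent.species]["nitrosonium+nitronium"]
        checks.append(QCCheck("NO+ + NO2+ fraction in dioxygenyl mode", frac,
                              thr, frac < thr))
    else:
        raise ValueError(f"no impurity rule for {reagent.species}")
    return QCReport(tuple(checks))


def qc_ratio_stability(ratios: Sequence[float],
                       tolerance: float = 0.02) -> QCReport:
    """Day-to-day stability of a reference fragment-ratio.

    Passes iff every measured ratio lies within ``tolerance`` (default 2%)
    of the series mean.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("empty ratio series")
    mean = float(ratios.mean())
    if mean == 0:
        raise ValueError("zero mean ratio")
    rel = np.abs(ratios / mean - 1.0)
    worst = float(rel.max())
    check = QCCheck("reference-peak ratio stability (max |dev| from mean)",
                    worst, tolerance, worst <= tolerance)
    return QCReport((check,))


def format_qc_report(report: QCReport) -> str:
    """Serialize a QC report as aligned key/value/threshold/status text."""
    lines = ["check\tvalue\tthreshold\tstatus"]
    for c in report.checks:
        lines.append(f"{c.name}\t{c.value:.5f}\t{c.threshold:.5f}"
                     f"\t{'pass' if c.passed else 'fail'}")
    return "\n".join(lines) + "\n"
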