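"""Peak-table container, delimited-text dialect, and transmission curves.

A peak table is a time x m/z matrix of detector count rates (cps) from
pre-integrated, centroided ToF channels, with per-bin drift voltage and a
humidity flag, plus run-level drift metadata.  The text dialect is:

    #reagent_ion<TAB>hydronium
    #pressure_mbar<TAB>2.30
    #temperature_C<TAB>110.0
    #drift_length_cm<TAB>9.6
    #reduced_mobility<TAB>2.76
    #transmission_corrected<TAB>0
    #columns<TAB>time_s<TAB>voltage_V<TAB>humidity<TAB>21.02<TAB>...
    0.0<TAB>600<TAB>1<TAB>1234.5<TAB>...

The detector transmission curve is a natural cubic spline through measured
(m/z, relative transmission) knots, max-normalized to 1 and clamped to the
end-knot values outside the knot range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from . import constants as C
from .kinetics import (DriftConditions, RateConstant, ReagentIon,
                       number_density, reaction_time)

__all__ = ["PeakTable", "TransmissionCurve", "PeakTableParseError",
           "read_peaktable", "write_peaktable", "build_transmission",
           "correct_transmission", "read_transmission",
           "write_transmission"]


class PeakTableParseError(ValueError):
    """Malformed peak-table file; carries the 1-based offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class PeakTable:
    times: np.ndarray          # (n_t,) seconds, strictly increasing
    channels: np.ndarray       # (n_mz,) Th, strictly increasing
    counts: np.ndarray         # (n_t, n_mz) cps, >= 0
    voltages: np.ndarray       # (n_t,) V
    humidity: np.ndarray       # (n_t,) bool, True = humid
    reagent_label: str = "hydronium"
    pressure_mbar: float = 2.30
    temperature_c: float = 110.0
    drift_length_cm: float = 9.6
    reduced_mobility: float = 2.76
    transmission_corrected: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.humidity = np.asarray(self.humidity, dtype=bool)
        if self.counts.shape != (self.times.size, self.channels.size):
            raise ValueError("counts shape inconsistent with time/channel axes")
        if self.voltages.shape != self.times.shape:
            raise ValueError("per-bin voltage length mismatch")
        if self.humidity.shape != self.times.shape:
            raise ValueError("per-bin humidity length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any(np.diff(self.channels) <= 0):
            raise ValueError("channels must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    # -- convenience -------------------------------------------------------

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15

    def conditions(self, voltage: float | None = None) -> DriftConditions:
        """Drift conditions for one bin (default: the first bin's voltage)."""
        u = float(self.voltages[0] if voltage is None else voltage)
        return DriftConditions(voltage=u, pressure=self.pressure_mbar,
                               temperature=self.temperature_k,
                               drift_length=self.drift_length_cm,
                               reduced_mobility=self.reduced_mobility)

    def channel_index(self, mz: float, tol: float = 0.005) -> int:
        i = int(np.argmin(np.abs(self.channels - mz)))
        if abs(self.channels[i] - mz) > tol:
            raise KeyError(f"channel {mz:.2f} Th not present in table")
        return i

    def trace(self, mz: float) -> np.ndarray:
        """Count-rate time trace of the channel nearest to ``mz``."""
        return self.counts[:, self.channel_index(mz)]

    def slice_time(self, mask: np.ndarray) -> "PeakTable":
        return replace(self, times=self.times[mask],
                       counts=self.counts[mask], voltages=self.voltages[mask],
                       humidity=self.humidity[mask],
                       metadata=dict(self.metadata))


# --------------------------------------------------------------------------
# text dialect
# --------------------------------------------------------------------------

_HEADER_KEYS = {
    "reagent_ion": ("reagent_label", str),
    "pressure_mbar": ("pressure_mbar", float),
    "temperature_C": ("temperature_c", float),
    "drift_length_cm": ("drift_length_cm", float),
    "reduced_mobility": ("reduced_mobility", float),
    "transmission_corrected": ("transmission_corrected",
                               lambda s: bool(int(s))),
}


def write_peaktable(table: PeakTable, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"#reagent_ion\t{table.reagent_label}",
        f"#pressure_mbar\t{table.pressure_mbar:g}",
        f"#temperature_C\t{table.temperature_c:g}",
        f"#drift_length_cm\t{table.drift_length_cm:g}",
        f"#reduced_mobility\t{table.reduced_mobility:g}",
        f"#transmission_corrected\t{int(table.transmission_corrected)}",
    ]
    for key in sorted(table.metadata):
        lines.append(f"#{key}\t{table.metadata[key]}")
    mz_labels = "\t".join(f"{mz:.2f}" for mz in table.channels)
    lines.append(f"#columns\ttime_s\tvoltage_V\thumidity\t{mz_labels}")
    for i in range(table.times.size):
        row = "\t".join(np.format_float_positional(v, precision=8, trim="-")
                        for v in table.counts[i])
        lines.append(f"{table.times[i]:g}\t{table.voltages[i]:g}"
                     f"\t{int(table.humidity[i])}\t{row}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_peaktable(path: str | Path) -> PeakTable:
    path = Path(path)
    meta: dict = {}
    channels: np.ndarray | None = None
    rows, times, volts, humid = [], [], [], []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(),
                                 start=1):
        if not raw.strip():
            continue
        if raw.startswith("#columns"):
            parts = raw.split("\t")
            if parts[1:4] != ["time_s", "voltage_V", "humidity"]:
                raise PeakTableParseError(
                    "#columns must start with time_s, voltage_V, humidity",
                    lineno)
            try:
                channels = np.array([float(p) for p in parts[4:]])
            except ValueError as exc:
                raise PeakTableParseError(f"bad m/z label: {exc}", lineno)
            if channels.size == 0:
                raise PeakTableParseError("no m/z channels declared", lineno)
            continue
        if raw.startswith("#"):
            key, _, value = raw[1:].partition("\t")
            if key not in _HEADER_KEYS:
                meta[key] = value
            else:
                attr, conv = _HEADER_KEYS[key]
                try:
                    meta[attr] = conv(value)
                except ValueError as exc:
                    raise PeakTableParseError(f"bad header value: {exc}",
                                              lineno)
            continue
        if channels is None:
            raise PeakTableParseError("data row before #columns line", lineno)
        parts = raw.split("\t")
        if len(parts) != 3 + channels.size:
            raise PeakTableParseError(
                f"expected {3 + channels.size} fields, got {len(parts)}",
                lineno)
        try:
            values = [float(p) for p in parts]
        except ValueError as exc:
            raise PeakTableParseError(f"non-numeric field: {exc}", lineno)
        if any(v < 0 for v in values[3:]):
            raise PeakTableParseError("negative count rate", lineno)
        times.append(values[0])
        volts.append(values[1])
        humid.append(bool(values[2]))
        rows.append(values[3:])
    if channels is None or not rows:
        raise PeakTableParseError("no data rows found")
    if np.any(np.diff(times) <= 0):
        raise PeakTableParseError("time axis not strictly increasing")
    known = {attr for attr, _ in _HEADER_KEYS.values()}
    kwargs = {k: v for k, v in meta.items() if k in known}
    extra = {k: v for k, v in meta.items() if k not in known}
    return PeakTable(times=np.array(times), channels=channels,
                     counts=np.array(rows), voltages=np.array(volts),
                     humidity=np.array(humid), metadata=extra, **kwargs)


# --------------------------------------------------------------------------
# transmission curve
# --------------------------------------------------------------------------

@dataclass
class TransmissionCurve:
    """Relative detector transmission vs m/z (natural cubic spline)."""

    knot_mz: np.ndarray
    knot_transmission: np.ndarray
    normalization: str = "max"
    _spline: CubicSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.knot_mz = np.asarray(self.knot_mz, dtype=float)
        self.knot_transmission = np.asarray(self.knot_transmission,
                                            dtype=float)
        if self.knot_mz.size < 3:
            raise ValueError("transmission curve needs at least 3 knots")
        if np.any(np.diff(self.knot_mz) <= 0):
            raise ValueError("knot m/z must be strictly increasing")
        if np.any(self.knot_transmission <= 0) or \
                np.any(self.knot_transmission > 1.0 + 1e-12):
            raise ValueError("knot transmission must lie in (0, 1]")
        self._spline = CubicSpline(self.knot_mz, self.knot_transmission,
                                   bc_type="natural")

    def __call__(self, mz) -> np.ndarray:
        """Evaluate, clamping to end-knot values outside the knot range."""
        mz = np.asarray(mz, dtype=float)
        clipped = np.clip(mz, self.knot_mz[0], self.knot_mz[-1])
        out = self._spline(clipped)
        # guard against spline overshoot below zero between sparse knots
        return np.maximum(out, 1e-6)


def write_transmission(curve: TransmissionCurve, path: str | Path) -> None:
    lines = ["#mz\ttransmission"]
    for m, t in zip(curve.knot_mz, curve.knot_transmission):
        lines.append(f"{m:.2f}\t{t:.6f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_transmission(path: str | Path) -> TransmissionCurve:
    mzs, ts = [], []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        m, t = raw.split("\t")
        mzs.append(float(m))
        ts.append(float(t))
    return TransmissionCurve(np.array(mzs), np.array(ts))


def build_transmission(measured: PeakTable, mix_concentration_ppbv: float,
                       references: dict[float, RateConstant],
                       reagent: ReagentIon) -> TransmissionCurve:
    """Fit the detector transmission curve from a certified reference mix.

    ``references`` maps each reference compound's product channel (Th) to
    its capture rate constant with the reagent ion.  For each channel the
    expected count rate at the known mixing ratio is computed from the
    quantitation relation (using the isotopologue-extrapolated, uncorrected
    primary signal); the knot value is measured/expected, max-normalized.
    """
    if len(references) < 3:
        raise ValueError("need at least 3 reference peaks to fit a curve")
    cond = measured.conditions()
    cond = DriftConditions(cond.voltage, cond.pressure, cond.temperature,
                           cond.drift_length, reagent.reduced_mobility)
    t = reaction_time(cond)
    n_a = (mix_concentration_ppbv * 1e-9
           * number_density(cond.pressure, cond.temperature))
    primary = float(np.mean(measured.trace(reagent.monitor_mz))
                    * reagent.isotope_factor)
    if primary <= 0:
        raise ValueError("no primary-ion signal in reference measurement")
    mzs = np.array(sorted(references))
    knots = np.empty_like(mzs)
    for i, mz in enumerate(mzs):
        expected = n_a * t * references[mz].value * primary
        if expected <= 0:
            raise ValueError(f"expected rate of 0 at channel {mz:.2f}")
        knots[i] = float(np.mean(measured.trace(mz))) / expected
    knots = knots / knots.max()
    return TransmissionCurve(mzs, knots)


def correct_transmission(table: PeakTable,
                         curve: TransmissionCurve) -> PeakTable:
    """Divide all channels by the relative transmission at their m/z."""
    if table.transmission_corrected:
        raise ValueError("table is already transmission-corrected")
    factors = curve(table.channels)
    out = replace(table, counts=table.counts / factors[None, :],
                  transmission_corrected=True,
                  metadata=dict(table.metadata))
    return out
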