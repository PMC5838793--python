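"""Forward simulation of every input the pipeline consumes.

The generators emulate the three bench experiments with known ground
truth: (1) a headspace spike followed by a stepwise E/N ramp, for
fragmentation-pattern work; (2) a diffusion-tube oven run with the three
reagent ions cycling in fixed blocks, for gravimetric validation; (3) a
certified aromatic mix at 100 ppbV, for the transmission curve.

The forward count model is the exact algebraic inverse of the quantitation
chain: per-channel source rates are the pseudo-first-order product of
analyte number density, reaction time, capture rate and reagent-ion
current, split by the programmed branching fractions; the detector applies
the transmission curve, clips saturating main beams, and adds Poisson
counting noise per time bin.  A fixed seed fixes every random draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from .fragmentation import RampSchedule
from .gravimetric import DiffusionRecord, mixing_ratio_from_rate
from .kinetics import (HYDRONIUM, HYDRONIUM_CLUSTER, REAGENT_IONS,
                       DriftConditions, MoleculeParams, RateConstant,
                       ReagentIon, ReagentSpecies, compute_EN,
                       effective_temperature, number_density, reaction_time,
                       su_capture_rate)
from .library import TRANSMISSION_REFERENCE_COMPOUNDS, load_compound_library
from .peaktable import PeakTable, TransmissionCurve

__all__ = ["SpikeKinetics", "PrimaryBeamConfig", "BranchingModel",
           "RampConfig", "DiffusionConfig", "CalibrationMixConfig",
           "simulate_ramp_run", "simulate_diffusion_run",
           "simulate_calibration_mix", "default_transmission_curve",
           "default_cluster_fraction", "reagent_blocks",
           "DEFAULT_BRANCHING", "analyte_rates"]


# --------------------------------------------------------------------------
# configuration blocks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeKinetics:
    """Double-exponential headspace response to a standard addition:
    c(t) = c_max (1 - exp(-(t-t0)/rise_tau)) exp(-(t-t0)/decay_tau)."""

    rise_tau: float = 5.0      # s
    decay_tau: float = 2000.0  # s; slow headspace depletion

    def shape(self, t: np.ndarray, t0: float) -> np.ndarray:
        dt = np.maximum(t - t0, 0.0)
        out = (1.0 - np.exp(-dt / self.rise_tau)) * np.exp(-dt / self.decay_tau)
        return np.where(t >= t0, out, 0.0)


@dataclass(frozen=True)
class PrimaryBeamConfig:
    """Reagent-ion beam: true current, detector cap, impurity level."""

    true_cps: float = 1e6        # source-level bare-ion current
    saturation_cap: float = 1e5  # detector clip on main channels
    impurity_fraction: float = 0.005  # clean-run impurity share


def default_cluster_fraction(td: float) -> float:
    """Hydronium-water-cluster share of the reagent current vs E/N.

    Linear falloff reaching ~20% at 48 Td and ~1% above 140 Td, matching
    the qualitative behavior that clusters are negligible above 120 Td and
    exceed 10% of the primary current at low reduced field.
    """
    return float(np.clip(0.30 - 0.002 * td, 0.01, 0.5))


class BranchingModel:
    """Percent product-ion shares vs E/N, piecewise linear through anchors.

    ``anchors`` maps integer Td values to {product m/z: percent}.  Columns
    are normalized to sum to exactly 100 (raising if a column is empty or
    negative); between anchors each channel is interpolated linearly in Td
    and the result renormalized.
    """

    def __init__(self, anchors: dict[int, dict[float, float]],
                 normalize: bool = True):
        if not anchors:
            raise ValueError("branching model needs at least one anchor")
        self.channels = sorted({mz for col in anchors.values() for mz in col})
        self._tds = np.array(sorted(anchors), dtype=float)
        rows = []
        for td in sorted(anchors):
            col = anchors[td]
            vals = np.array([max(float(col.get(mz, 0.0)), 0.0)
                             for mz in self.channels])
            if any(v < 0 for v in col.values()):
                raise ValueError("negative branching anchor")
            s = vals.sum()
            if s <= 0:
                raise ValueError(f"empty branching anchor at {td} Td")
            if not normalize and abs(s - 100.0) > 0.5:
                raise ValueError(f"anchor at {td} Td sums to {s}, not 100")
            rows.append(100.0 * vals / s)
        self._grid = np.array(rows)  # (n_anchor, n_channel)

    def fractions(self, td: float) -> dict[float, float]:
        """Fractional (0-1) shares per channel at the given Td."""
        td = float(np.clip(td, self._tds[0], self._tds[-1]))
        vals = np.array([np.interp(td, self._tds, self._grid[:, j])
                         for j in range(len(self.channels))])
        vals = vals / vals.sum()
        return dict(zip(self.channels, vals))


# Default per-compound branching anchors, patterned on the measured
# fragmentation of the study compounds (columns renormalized to 100).
DEFAULT_BRANCHING: dict[tuple[str, str], dict[int, dict[float, float]]] = {
    ("decanal", "nitrosonium"): {
        144: {155.14: 13, 137.13: 8, 95.09: 15, 81.08: 13, 67.05: 5,
              57.07: 8, 43.04: 9, 41.03: 19, 39.02: 9},
        132: {155.14: 52, 137.13: 10, 95.09: 12, 81.08: 10, 57.07: 11,
              43.04: 13, 41.03: 12},
        120: {155.14: 59, 137.13: 10, 95.09: 7, 81.08: 6, 57.07: 8,
              43.04: 9},
        108: {155.14: 91, 137.13: 9},
        96: {155.14: 94, 137.13: 6},
        84: {173.16: 4, 155.14: 90, 137.13: 5},
        72: {173.16: 9, 155.14: 86, 137.13: 5},
        48: {191.16: 10, 173.16: 22, 155.14: 63, 137.13: 4},
    },
    ("hexanoic acid", "hydronium"): {
        144: {117.09: 60, 71.09: 6, 43.05: 14, 41.04: 12, 29.02: 8},
        132: {117.09: 60, 99.08: 6, 71.09: 9, 43.05: 17, 41.04: 7},
        120: {117.09: 61, 99.08: 11, 71.09: 14, 43.05: 13},
        108: {117.09: 67, 99.08: 19, 71.09: 15},
        96: {117.09: 69, 99.08: 23, 71.09: 8},
        84: {135.09: 6, 117.09: 73, 99.08: 21},
        72: {135.09: 13, 117.09: 73, 99.08: 14},
        48: {135.09: 33, 117.09: 67},
    },
    ("4-ethyl-phenol", "dioxygenyl"): {
        144: {122.06: 22, 107.05: 78},
        132: {122.06: 30, 107.05: 70},
        120: {123.08: 5, 122.06: 32, 107.05: 62},
        108: {123.08: 7, 122.06: 33, 107.05: 59},
        96: {123.08: 9, 122.06: 34, 107.05: 56},
        84: {123.08: 12, 122.06: 34, 107.05: 53},
        72: {123.08: 16, 122.06: 34, 107.05: 50},
        48: {123.08: 27, 122.06: 31, 107.05: 42},
    },
    # short-chain aldehyde with a strong sensitivity gain at low E/N
    ("butanal", "nitrosonium"): {
        144: {71.07: 50, 43.05: 50},
        120: {71.07: 75, 43.05: 25},
        96: {71.07: 90, 43.05: 10},
        84: {71.07: 92, 43.05: 8},
        72: {71.07: 95, 43.05: 3, 89.08: 2},
        48: {71.07: 85, 43.05: 0, 89.08: 15},
    },
    ("phenol", "hydronium"): {144: {95.05: 100}, 48: {95.05: 95, 113.06: 5}},
    ("phenol", "nitrosonium"): {144: {94.04: 100}, 48: {94.04: 100}},
    ("phenol", "dioxygenyl"): {
        144: {94.04: 95, 95.05: 5}, 84: {94.04: 85, 95.05: 15},
        48: {94.04: 70, 95.05: 30}},
    ("pentanoic acid", "hydronium"): {
        144: {103.08: 65, 85.06: 25, 43.04: 10},
        84: {103.08: 80, 85.06: 15, 121.09: 5},
        48: {103.08: 70, 121.09: 30}},
    ("butanoic acid", "hydronium"): {
        144: {89.06: 65, 71.05: 25, 43.04: 10},
        84: {89.06: 80, 71.05: 15, 107.07: 5},
        48: {89.06: 70, 107.07: 30}},
}


def default_transmission_curve() -> TransmissionCurve:
    """Smooth log-normal-shaped detector transmission, peaked near 120 Th."""
    knots = np.array([20.0, 40.0, 60.0, 80.0, 100.0, 120.0, 140.0, 160.0,
                      180.0, 200.0])
    vals = np.exp(-0.5 * (np.log(knots / 120.0) / 0.85) ** 2)
    return TransmissionCurve(knots, vals / vals.max())


# --------------------------------------------------------------------------
# shared forward machinery
# --------------------------------------------------------------------------

def analyte_rates(compound: MoleculeParams, reagent: ReagentIon,
                  conditions: DriftConditions,
                  k_override: float | None = None
                  ) -> tuple[RateConstant, RateConstant]:
    """Capture rates of the analyte with a reagent ion and (for hydronium)
    its water cluster, at the Wannier effective temperature of each pair."""
    teff = effective_temperature(conditions, reagent.ion_mass,
                                 neutral_mass=compound.molar_mass)
    if k_override is not None:
        k_p = RateConstant(k_override, teff)
    else:
        k_p = su_capture_rate(compound, reagent.ion_mass, teff)
    teff_c = effective_temperature(conditions, HYDRONIUM_CLUSTER.ion_mass,
                                   neutral_mass=compound.molar_mass)
    k_c = su_capture_rate(compound, HYDRONIUM_CLUSTER.ion_mass, teff_c)
    return k_p, k_c


def _reagent_channels(reagent: ReagentIon, cluster: bool) -> list[float]:
    chans = [reagent.main_mz, reagent.monitor_mz]
    if cluster:
        chans += [HYDRONIUM_CLUSTER.main_mz, HYDRONIUM_CLUSTER.monitor_mz]
    return chans


def _beam_source_rates(reagent: ReagentIon, beam: PrimaryBeamConfig,
                       cluster_frac: float) -> dict[float, float]:
    """Source-level (pre-transmission) cps of the reagent-beam channels."""
    s_p = beam.true_cps
    rates = {reagent.main_mz: s_p,
             reagent.monitor_mz: s_p / reagent.isotope_factor}
    if reagent.species is ReagentSpecies.HYDRONIUM and cluster_frac > 0:
        s_c = s_p * cluster_frac / (1.0 - cluster_frac)
        rates[HYDRONIUM_CLUSTER.main_mz] = s_c
        rates[HYDRONIUM_CLUSTER.monitor_mz] = \
            s_c / HYDRONIUM_CLUSTER.isotope_factor
    return rates


_IMPURITY_CHANNEL = {
    ReagentSpecies.HYDRONIUM: 31.99,     # O2+
    ReagentSpecies.NITROSONIUM: 45.99,   # NO2+
    ReagentSpecies.DIOXYGENYL: 30.00,    # NO+
}


def _emit(counts_cps: np.ndarray, channels: np.ndarray, main_channels,
          cap: float, noise: bool, rng: np.random.Generator,
          dt: float) -> np.ndarray:
    """Apply Poisson noise per bin, then clip saturating main channels."""
    out = counts_cps
    if noise:
        out = rng.poisson(np.maximum(out, 0.0) * dt).astype(float) / dt
    for mz in main_channels:
        j = int(np.argmin(np.abs(channels - mz)))
        if abs(channels[j] - mz) <= 0.005:
            out[:, j] = np.minimum(out[:, j], cap)
    return out


# --------------------------------------------------------------------------
# ramp run
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RampConfig:
    """Study conditions of a spike + E/N-ramp fragmentation experiment."""

    seed: int = 0
    compound_name: str = "decanal"
    reagent_label: str = "nitrosonium"
    # headspace of a percent-level aqueous standard reaches ppm-scale vapor
    # mixing ratios; 1000 ppbV puts the product-ion sum at the 1e4 cps scale
    true_concentration_ppbv: float = 1000.0
    schedule: RampSchedule = field(default_factory=lambda: RampSchedule(
        step_voltages=(600, 550, 500, 450, 400, 350, 300, 200)))
    spike: SpikeKinetics = field(default_factory=SpikeKinetics)
    beam: PrimaryBeamConfig = field(default_factory=PrimaryBeamConfig)
    branching: BranchingModel | None = None   # default: library pattern
    pressure_mbar: float = 2.30
    temperature_c: float = 110.0
    drift_length_cm: float = 9.6
    noise: bool = True
    dt: float = 1.0
    humid: bool = True
    confounder_mz: float | None = 83.09  # drifts independently of the spike
    confounder_cps: float = 500.0
    flat_channels: tuple[float, ...] = (61.03, 129.13)
    flat_cps: float = 50.0
    k_override: float | None = None


def _resolve_branching(cfg_branching, compound_name, reagent_label
                       ) -> BranchingModel:
    if cfg_branching is not None:
        return cfg_branching
    key = (compound_name, reagent_label)
    if key not in DEFAULT_BRANCHING:
        raise ValueError(f"no default branching pattern for {key}; supply "
                         "a BranchingModel")
    return BranchingModel(DEFAULT_BRANCHING[key])


def simulate_ramp_run(config: RampConfig) -> PeakTable:
    """Forward-simulate a standard-addition spike under a stepped E/N ramp."""
    rng = np.random.default_rng(config.seed)
    lib = load_compound_library()
    compound = lib[config.compound_name].params
    reagent = REAGENT_IONS[config.reagent_label]
    branching = _resolve_branching(config.branching, config.compound_name,
                                   config.reagent_label)
    curve = default_transmission_curve()
    sched = config.schedule
    n_bins = int(round(sched.total_duration / config.dt))
    times = np.arange(n_bins) * config.dt
    step_idx = np.minimum((times // sched.step_duration).astype(int),
                          len(sched.step_voltages) - 1)
    voltages = np.array([sched.step_voltages[i] for i in step_idx],
                        dtype=float)

    is_hydronium = reagent.species is ReagentSpecies.HYDRONIUM
    product_channels = list(branching.channels)
    channels = sorted(set(
        product_channels + _reagent_channels(reagent, is_hydronium)
        + [_IMPURITY_CHANNEL[reagent.species]]
        + list(config.flat_channels)
        + ([config.confounder_mz] if config.confounder_mz else [])))
    channels = np.array(channels)
    counts = np.zeros((n_bins, channels.size))

    c_shape = config.spike.shape(times, sched.spike_time)
    n_gas = number_density(config.pressure_mbar, config.temperature_c + 273.15)

    for v in dict.fromkeys(sched.step_voltages):
        mask = voltages == v
        cond = DriftConditions(float(v), config.pressure_mbar,
                               config.temperature_c + 273.15,
                               config.drift_length_cm,
                               reagent.reduced_mobility)
        td = compute_EN(cond)
        t_rx = reaction_time(cond)
        k_p, k_c = analyte_rates(compound, reagent, cond, config.k_override)
        f_cluster = default_cluster_fraction(td) if is_hydronium else 0.0
        beam = _beam_source_rates(reagent, config.beam, f_cluster)
        denom = k_p.value * config.beam.true_cps
        if is_hydronium and f_cluster > 0:
            denom += k_c.value * beam[HYDRONIUM_CLUSTER.main_mz]
        n_a = config.true_concentration_ppbv * 1e-9 * n_gas * c_shape[mask]
        total_products = n_a * t_rx * denom  # cps, source level
        fracs = branching.fractions(round(td))
        for mz, frac in fracs.items():
            j = int(np.argmin(np.abs(channels - mz)))
            counts[mask, j] += frac * total_products * float(curve(mz))
        for mz, s in beam.items():
            j = int(np.argmin(np.abs(channels - mz)))
            counts[mask, j] += s * float(curve(mz))
        imp_mz = _IMPURITY_CHANNEL[reagent.species]
        j = int(np.argmin(np.abs(channels - imp_mz)))
        counts[mask, j] += (config.beam.impurity_fraction
                            * config.beam.true_cps * float(curve(imp_mz)))

    for mz in config.flat_channels:
        j = int(np.argmin(np.abs(channels - mz)))
        counts[:, j] += config.flat_cps
    if config.confounder_mz is not None:
        j = int(np.argmin(np.abs(channels - config.confounder_mz)))
        counts[:, j] += (config.confounder_cps * times / times[-1])

    main = [reagent.main_mz] + ([HYDRONIUM_CLUSTER.main_mz]
                                if is_hydronium else [])
    counts = _emit(counts, channels, main, config.beam.saturation_cap,
                   config.noise, rng, config.dt)
    return PeakTable(times=times, channels=channels, counts=counts,
                     voltages=voltages,
                     humidity=np.full(n_bins, config.humid),
                     reagent_label=config.reagent_label,
                     pressure_mbar=config.pressure_mbar,
                     temperature_c=config.temperature_c,
                     drift_length_cm=config.drift_length_cm,
                     reduced_mobility=reagent.reduced_mobility)


# --------------------------------------------------------------------------
# diffusion run
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionConfig:
    """Study conditions of a diffusion-tube oven run."""

    seed: int = 0
    compound_name: str = "decanal"
    release_rate_ng_min: float = 3969.0
    flow_sccm: float = 2000.0
    oven_temperature_c: float = 60.0
    reagent_cycle: tuple[str, ...] = ("hydronium", "nitrosonium",
                                      "dioxygenyl")
    block_duration_s: float = 300.0  # 5 min per reagent ion
    n_cycles: int = 1
    drift_voltage: float = 350.0     # 84 Td operating point
    pressure_mbar: float = 2.30
    temperature_c: float = 110.0
    drift_length_cm: float = 9.6
    beam: PrimaryBeamConfig = field(default_factory=PrimaryBeamConfig)
    noise: bool = True
    dt: float = 1.0
    replicate_id: str = "1"
    k_override: float | None = None


def simulate_diffusion_run(config: DiffusionConfig
                           ) -> tuple[PeakTable, DiffusionRecord]:
    """Forward-simulate a steady diffusion-tube release with cycling ions.

    The mixing ratio at the instrument follows from the programmed release
    rate, the oven flow and the standard molar volume; the paired
    gravimetric record carries the exactly consistent weight loss.
    """
    rng = np.random.default_rng(config.seed)
    lib = load_compound_library()
    entry = lib[config.compound_name]
    compound = entry.params
    curve = default_transmission_curve()
    ppbv = mixing_ratio_from_rate(config.release_rate_ng_min,
                                  config.flow_sccm, compound.molar_mass)
    n_gas = number_density(config.pressure_mbar, config.temperature_c + 273.15)
    n_a = ppbv * 1e-9 * n_gas

    n_blocks = config.n_cycles * len(config.reagent_cycle)
    bins_per_block = int(round(config.block_duration_s / config.dt))
    n_bins = n_blocks * bins_per_block
    times = np.arange(n_bins) * config.dt
    voltages = np.full(n_bins, float(config.drift_voltage))
    block_labels = [config.reagent_cycle[b % len(config.reagent_cycle)]
                    for b in range(n_blocks)]

    all_channels: set[float] = set()
    for label in set(block_labels):
        reagent = REAGENT_IONS[label]
        hyd = reagent.species is ReagentSpecies.HYDRONIUM
        all_channels.update(_reagent_channels(reagent, hyd))
        all_channels.add(_IMPURITY_CHANNEL[reagent.species])
        prods = _diffusion_products(entry.name, label)
        all_channels.update(prods)
    channels = np.array(sorted(all_channels))
    counts = np.zeros((n_bins, channels.size))

    cond_cache: dict[str, DriftConditions] = {}
    for b, label in enumerate(block_labels):
        reagent = REAGENT_IONS[label]
        hyd = reagent.species is ReagentSpecies.HYDRONIUM
        cond = cond_cache.setdefault(label, DriftConditions(
            config.drift_voltage, config.pressure_mbar,
            config.temperature_c + 273.15, config.drift_length_cm,
            reagent.reduced_mobility))
        td = compute_EN(cond)
        t_rx = reaction_time(cond)
        k_p, k_c = analyte_rates(compound, reagent, cond, config.k_override)
        f_cluster = default_cluster_fraction(td) if hyd else 0.0
        beam = _beam_source_rates(reagent, config.beam, f_cluster)
        denom = k_p.value * config.beam.true_cps
        if hyd and f_cluster > 0:
            denom += k_c.value * beam[HYDRONIUM_CLUSTER.main_mz]
        total = n_a * t_rx * denom
        sl = slice(b * bins_per_block, (b + 1) * bins_per_block)
        for mz, frac in _diffusion_products(entry.name, label).items():
            j = int(np.argmin(np.abs(channels - mz)))
            counts[sl, j] += frac * total * float(curve(mz))
        for mz, s in beam.items():
            j = int(np.argmin(np.abs(channels - mz)))
            counts[sl, j] += s * float(curve(mz))
        imp = _IMPURITY_CHANNEL[reagent.species]
        j = int(np.argmin(np.abs(channels - imp)))
        counts[sl, j] += (config.beam.impurity_fraction
                          * config.beam.true_cps * float(curve(imp)))

    main = {REAGENT_IONS[l].main_mz for l in set(block_labels)}
    main |= {HYDRONIUM_CLUSTER.main_mz} if "hydronium" in block_labels else set()
    counts = _emit(counts, channels, sorted(main),
                   config.beam.saturation_cap, config.noise, rng, config.dt)

    blocks = ";".join(
        f"{b * config.block_duration_s:g}:{(b + 1) * config.block_duration_s:g}"
        f":{label}" for b, label in enumerate(block_labels))
    table = PeakTable(times=times, channels=channels, counts=counts,
                      voltages=voltages,
                      humidity=np.zeros(n_bins, dtype=bool),
                      reagent_label=block_labels[0],
                      pressure_mbar=config.pressure_mbar,
                      temperature_c=config.temperature_c,
                      drift_length_cm=config.drift_length_cm,
                      reduced_mobility=REAGENT_IONS[
                          block_labels[0]].reduced_mobility,
                      metadata={"reagent_blocks": blocks})
    duration_min = n_bins * config.dt / 60.0
    record = DiffusionRecord(
        compound=compound.name, molar_mass=compound.molar_mass,
        oven_flow=config.flow_sccm,
        oven_temperature=config.oven_temperature_c + 273.15,
        weight_loss=config.release_rate_ng_min * duration_min * 1e-6,
        duration=duration_min, replicate_id=config.replicate_id)
    return table, record


def _diffusion_products(compound_name: str, reagent_label: str
                        ) -> dict[float, float]:
    """Product-channel fractions at the 84 Td operating point."""
    key = (compound_name, reagent_label)
    if key in DEFAULT_BRANCHING:
        return BranchingModel(DEFAULT_BRANCHING[key]).fractions(84.0)
    # fall back to the first library candidate channel as sole product
    lib = load_compound_library()
    chans = lib[compound_name].product_channels.get(reagent_label, ())
    if not chans:
        raise ValueError(f"no product channels known for {key}")
    return {chans[0]: 1.0}


def reagent_blocks(table: PeakTable) -> list[tuple[str, PeakTable]]:
    """Split a cycling-reagent run into (label, sub-table) blocks."""
    spec = table.metadata.get("reagent_blocks")
    if not spec:
        return [(table.reagent_label, table)]
    out = []
    for part in spec.split(";"):
        start, stop, label = part.split(":")
        mask = (table.times >= float(start)) & (table.times < float(stop))
        sub = table.slice_time(mask)
        sub.reagent_label = label
        sub.reduced_mobility = REAGENT_IONS[label].reduced_mobility
        out.append((label, sub))
    return out


# --------------------------------------------------------------------------
# calibration mix
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationMixConfig:
    """Certified aromatic mix (every member at the same mixing ratio)."""

    seed: int = 0
    concentration_ppbv: float = 100.0
    drift_voltage: float = 600.0  # 144 Td: cluster-free hydronium operation
    pressure_mbar: float = 2.30
    temperature_c: float = 110.0
    drift_length_cm: float = 9.6
    duration_s: float = 60.0
    beam: PrimaryBeamConfig = field(default_factory=PrimaryBeamConfig)
    transmission: TransmissionCurve | None = None
    noise: bool = True
    dt: float = 1.0


def simulate_calibration_mix(config: CalibrationMixConfig) -> PeakTable:
    """Forward-simulate the transmission-reference aromatic mix (hydronium)."""
    rng = np.random.default_rng(config.seed)
    lib = load_compound_library()
    reagent = HYDRONIUM
    curve = (config.transmission if config.transmission is not None
             else default_transmission_curve())
    cond = DriftConditions(config.drift_voltage, config.pressure_mbar,
                           config.temperature_c + 273.15,
                           config.drift_length_cm, reagent.reduced_mobility)
    t_rx = reaction_time(cond)
    n_a = (config.concentration_ppbv * 1e-9
           * number_density(config.pressure_mbar, config.temperature_c + 273.15))
    n_bins = int(round(config.duration_s / config.dt))
    times = np.arange(n_bins) * config.dt

    ref_channels: dict[float, float] = {}
    for name in TRANSMISSION_REFERENCE_COMPOUNDS:
        entry = lib[name]
        mz = entry.product_channels["hydronium"][0]
        k_p, _ = analyte_rates(entry.params, reagent, cond)
        ref_channels[mz] = n_a * t_rx * k_p.value * config.beam.true_cps

    beam = _beam_source_rates(reagent, config.beam, cluster_frac=0.0)
    channels = np.array(sorted(set(ref_channels) | set(beam)))
    counts = np.zeros((n_bins, channels.size))
    for mz, s in {**ref_channels, **beam}.items():
        j = int(np.argmin(np.abs(channels - mz)))
        counts[:, j] += s * float(curve(mz))
    counts = _emit(counts, channels, [reagent.main_mz],
                   config.beam.saturation_cap, config.noise, rng, config.dt)
    return PeakTable(times=times, channels=channels, counts=counts,
                     voltages=np.full(n_bins, config.drift_voltage),
                     humidity=np.zeros(n_bins, dtype=bool),
                     reagent_label="hydronium",
                     pressure_mbar=config.pressure_mbar,
                     temperature_c=config.temperature_c,
                     drift_length_cm=config.drift_length_cm,
                     reduced_mobility=reagent.reduced_mobility)
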