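"""E/N-ramp segmentation, product-ion attribution, and branching ratios.

A fragmentation run spikes a single compound into a humid headspace and
steps the drift voltage downward in one-minute plateaus.  Product channels
are attributed to the parent by their time evolution: they rise sharply
after the spike and track the total-product trace while drift conditions
are constant.  Per-plateau branching ratios are the transmission-corrected
channel means normalized to percent of the attributed-product sum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import compute_EN
from .peaktable import PeakTable, TransmissionCurve

__all__ = ["RampSchedule", "BranchingTable", "segment_ramp",
           "attribute_products", "branching_ratios", "humidity_shift",
           "DEFAULT_EXCLUDED_CHANNELS"]

log = logging.getLogger(__name__)

#: Reagent-beam and impurity channels never considered as products.
DEFAULT_EXCLUDED_CHANNELS = (19.02, 21.02, 30.00, 30.99, 31.99, 33.99,
                             37.03, 39.03, 45.99)


@dataclass(frozen=True)
class RampSchedule:
    """Stepwise drift-voltage program with a standard-addition spike."""

    step_voltages: tuple[float, ...]
    step_duration: float = 60.0   # s
    spike_time: float = 30.0      # s from run start

    def __post_init__(self) -> None:
        if len(self.step_voltages) < 1:
            raise ValueError("need at least one ramp step")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be > 0")

    @property
    def total_duration(self) -> float:
        return self.step_duration * len(self.step_voltages)


@dataclass
class BranchingTable:
    """Per-product, per-E/N relative abundances (percent).

    ``data`` is indexed by product m/z with one column per integer Td
    label; values are unrounded percentages (NaN marks absent / below the
    reporting threshold).  Within each valid column the stored percentages
    sum to 100.
    """

    compound: str
    reagent_label: str
    data: pd.DataFrame
    invalid_steps: tuple[int, ...] = ()
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 100 + 1e-9:
                raise ValueError("branching percentages must lie in [0, 100]")

    def rounded(self) -> pd.DataFrame:
        """Integer-rounded view, as branching tables are reported."""
        return self.data.round(0).astype("Int64")

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "label",
                   [self.labels.get(mz, "") for mz in out.index])
        out.index.name = "product_mz"
        header = (f"#compound\t{self.compound}\n"
                  f"#reagent_ion\t{self.reagent_label}\n")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            out.to_csv(fh, sep="\t", float_format="%.3f", na_rep="-")


def _step_boundaries(voltages: np.ndarray) -> list[slice]:
    """Contiguous runs of constant per-bin voltage, in time order."""
    edges = np.flatnonzero(np.diff(voltages) != 0) + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [voltages.size]))
    return [slice(a, b) for a, b in zip(starts, stops)]


def segment_ramp(table: PeakTable, schedule: RampSchedule,
                 settle_s: float = 10.0,
                 spike_settle_s: float = 15.0) -> list[PeakTable]:
    """Split a ramp run into one trimmed slice per voltage plateau.

    The first ``settle_s`` seconds of each plateau are discarded as a
    settling window; in the plateau containing the spike, bins before
    ``spike_time + spike_settle_s`` are discarded as well (pre-addition
    baseline and headspace equilibration).
    """
    runs = _step_boundaries(table.voltages)
    observed = [float(table.voltages[r][0]) for r in runs]
    if observed != [float(v) for v in schedule.step_voltages]:
        raise ValueError(
            f"voltage trace {observed} inconsistent with schedule "
            f"{list(schedule.step_voltages)}")
    slices = []
    for r in runs:
        t = table.times
        start_time = t[r][0]
        mask = np.zeros(t.size, dtype=bool)
        mask[r] = True
        mask &= t >= start_time + settle_s
        if t[r][0] <= schedule.spike_time <= t[r][-1]:
            mask &= t >= schedule.spike_time + spike_settle_s
        if not mask.any():
            raise ValueError("settling window longer than a ramp step")
        slices.append(table.slice_time(mask))
    return slices


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r with a degenerate-variance convention.

    Two (numerically) constant traces are treated as perfectly
    proportional (r = 1); one constant trace against a varying one as
    uncorrelated (r = 0).
    """
    sa, sb = np.std(a), np.std(b)
    scale_a = max(abs(float(np.mean(a))), 1.0)
    scale_b = max(abs(float(np.mean(b))), 1.0)
    flat_a, flat_b = sa < 1e-9 * scale_a, sb < 1e-9 * scale_b
    if flat_a and flat_b:
        return 1.0
    if flat_a or flat_b:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def attribute_products(table: PeakTable, spike_time: float,
                       rise_sigma: float = 5.0,
                       corr_threshold: float = 0.95,
                       exclude_channels=DEFAULT_EXCLUDED_CHANNELS,
                       channel_tol: float = 0.005) -> list[float]:
    """Channels attributable to the spiked parent compound.

    A channel is a product if its post-spike rise exceeds ``rise_sigma``
    baseline Poisson standard deviations and its trace tracks the
    total-product trace: Pearson r above ``corr_threshold`` either in the
    spike window (spike to the end of the plateau containing it) or, for
    channels that only switch on at later plateaus, within some plateau
    where the channel is significantly elevated.  Channels rising
    independently of the spike fail the correlation rule.
    """
    t = table.times
    if not (t[0] <= spike_time <= t[-1]):
        raise ValueError("spike_time outside the run's time range")
    pre = t < spike_time
    if not pre.any():
        raise ValueError("no pre-spike baseline available")
    dt = float(np.median(np.diff(t)))
    runs = _step_boundaries(table.voltages)
    spike_run = next(r for r in runs
                     if t[r][0] <= spike_time <= t[r][-1])
    window = (t >= spike_time) & (t <= t[spike_run][-1])

    excluded = np.zeros(table.channels.size, dtype=bool)
    for mz in exclude_channels:
        hit = np.abs(table.channels - mz) <= channel_tol
        excluded |= hit
    candidates = np.flatnonzero(~excluded)

    base_mean = table.counts[pre].mean(axis=0)
    base_sd = np.sqrt(np.maximum(base_mean, 1.0) / dt)

    step_means = np.stack([table.counts[r].mean(axis=0) for r in runs])
    rise = step_means - base_mean[None, :]
    rising = {int(i) for i in candidates
              if rise[:, i].max() > rise_sigma * base_sd[i]}
    if not rising:
        warnings.warn("no channel passed the post-spike rise threshold",
                      stacklevel=2)
        return []

    ref = table.counts[:, sorted(rising)].sum(axis=1)
    attributed: set[int] = set()
    for i in sorted(rising):
        ch_win = table.counts[window, i] - base_mean[i]
        win_rise = float(ch_win.mean())
        if win_rise > rise_sigma * base_sd[i]:
            r = _pearson(ch_win, ref[window])
            if r >= corr_threshold:
                attributed.add(i)

    # late-onset channels: confirmed by within-plateau proportionality to
    # the already-attributed products (exact for noiseless data; noisy
    # near-flat plateaus may not confirm)
    if attributed:
        ref_att = table.counts[:, sorted(attributed)].sum(axis=1)
        for i in sorted(rising - attributed):
            for j, r_ in enumerate(runs):
                if rise[j, i] <= rise_sigma * base_sd[i]:
                    continue
                if t[r_][-1] <= spike_time:
                    continue
                rr = _pearson(table.counts[r_, i], ref_att[r_])
                if rr >= corr_threshold:
                    attributed.add(i)
                    break
    if not attributed:
        warnings.warn("no channel passed the attribution correlation rule",
                      stacklevel=2)
    return [float(table.channels[i]) for i in sorted(attributed)]


def branching_ratios(slices: list[PeakTable], products: list[float],
                     curve: TransmissionCurve | None = None,
                     compound: str = "", reporting_threshold: float = 2.0,
                     merge_map: dict[float, list[float]] | None = None,
                     baseline: dict[float, float] | None = None
                     ) -> BranchingTable:
    """Per-plateau branching ratios of the attributed product channels.

    Each slice contributes one integer-Td column: the mean transmission-
    corrected count rate per product (optionally baseline-subtracted and
    with declared isotopologue channels merged into their parent) is
    normalized to percent of the product-channel sum.  Products below
    ``reporting_threshold`` percent in every plateau are dropped.  Plateaus
    with zero total product signal are marked invalid and omitted.
    """
    if not products:
        raise ValueError("empty attributed product set")
    merge_map = merge_map or {}
    baseline = baseline or {}
    columns: dict[int, np.ndarray] = {}
    invalid: list[int] = []
    for sl in slices:
        cond = sl.conditions(voltage=float(sl.voltages[0]))
        td = int(round(compute_EN(cond)))
        means = []
        for mz in products:
            chans = [mz] + list(merge_map.get(mz, []))
            total = 0.0
            for ch in chans:
                raw = float(np.mean(sl.trace(ch))) - baseline.get(ch, 0.0)
                if not sl.transmission_corrected and curve is not None:
                    raw /= float(curve(ch))
                total += max(raw, 0.0)
            means.append(total)
        means = np.array(means)
        tot = means.sum()
        if tot <= 0:
            invalid.append(td)
            continue
        columns[td] = 100.0 * means / tot
    if not columns:
        raise ValueError("no valid ramp step (zero product signal "
                         "throughout)")
    frame = pd.DataFrame(columns, index=pd.Index(products,
                                                 name="product_mz"))
    # columns ordered by decreasing Td, the conventional reporting order
    frame = frame[sorted(frame.columns, reverse=True)]
    keep = (frame >= reporting_threshold).any(axis=1)
    frame = frame.where(frame >= reporting_threshold)
    frame = frame[keep.to_numpy()]
    reagent = slices[0].reagent_label if slices else ""
    return BranchingTable(compound=compound, reagent_label=reagent,
                          data=frame, invalid_steps=tuple(invalid))


def humidity_shift(humid: BranchingTable, dry: BranchingTable) -> pd.DataFrame:
    """Element-wise branching change (dry minus humid), percentage points."""
    if not humid.data.index.equals(dry.data.index) or \
            list(humid.data.columns) != list(dry.data.columns):
        raise ValueError("humid and dry tables have mismatched structure")
    return dry.data.fillna(0.0) - humid.data.fillna(0.0)
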