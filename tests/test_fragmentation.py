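"""Ramp segmentation, product attribution, and branching-ratio recovery."""

import numpy as np
import pandas as pd
import pytest

from ptrkit.fragmentation import (BranchingTable, RampSchedule,
                                  attribute_products, branching_ratios,
                                  humidity_shift, segment_ramp)
from ptrkit.peaktable import PeakTable, correct_transmission
from ptrkit.synthetic import (BranchingModel, DEFAULT_BRANCHING, RampConfig,
                              SpikeKinetics, default_transmission_curve,
                              simulate_ramp_run)
from ptrkit.workflow import analyze_ramp_run

SCHEDULE = RampSchedule((600, 550, 500, 450, 400, 350, 300, 200))


class TestSegmentRamp:
    def test_eight_steps_with_correct_voltages(self, noiseless_ramp):
        cfg, table = noiseless_ramp
        slices = segment_ramp(table, cfg.schedule)
        assert len(slices) == 8
        for sl, v in zip(slices, cfg.schedule.step_voltages):
            assert np.all(sl.voltages == v)

    def test_settling_window_trimmed(self, noiseless_ramp):
        cfg, table = noiseless_ramp
        slices = segment_ramp(table, cfg.schedule, settle_s=10.0)
        for i, sl in enumerate(slices[1:], start=1):
            step_start = i * cfg.schedule.step_duration
            assert sl.times[0] >= step_start + 10.0
            assert sl.times[0] <= step_start + 11.0  # within one bin

    def test_spike_step_trims_baseline(self, noiseless_ramp):
        cfg, table = noiseless_ramp
        slices = segment_ramp(table, cfg.schedule, spike_settle_s=15.0)
        assert slices[0].times[0] >= cfg.schedule.spike_time + 15.0

    def test_single_step_run(self):
        cfg = RampConfig(seed=0, noise=False,
                         schedule=RampSchedule((350,), step_duration=120.0))
        table = simulate_ramp_run(cfg)
        slices = segment_ramp(table, cfg.schedule)
        assert len(slices) == 1
        assert np.all(slices[0].voltages == 350)

    def test_inconsistent_schedule_rejected(self, noiseless_ramp):
        _, table = noiseless_ramp
        bad = RampSchedule((600, 550, 500))
        with pytest.raises(ValueError):
            segment_ramp(table, bad)


class TestAttribution:
    def test_programmed_products_only(self):
        """Three programmed channels recovered; flat channels rejected."""
        anchors = {144: {101.10: 60, 83.09: 30, 55.05: 10}}
        cfg = RampConfig(seed=11, compound_name="hexanal",
                         reagent_label="nitrosonium",
                         branching=BranchingModel(anchors),
                         schedule=RampSchedule((600,), step_duration=120.0),
                         confounder_mz=None,
                         flat_channels=(45.03, 61.03, 75.04, 91.05, 129.13))
        table = simulate_ramp_run(cfg)
        corrected = correct_transmission(table,
                                         default_transmission_curve())
        products = attribute_products(corrected, cfg.schedule.spike_time)
        assert products == [55.05, 83.09, 101.10]

    def test_flat_run_yields_empty_set(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50.0, size=(120, 4)).astype(float)
        table = PeakTable(times=np.arange(120.0),
                          channels=np.array([55.05, 83.09, 101.10, 129.13]),
                          counts=counts, voltages=np.full(120, 600.0),
                          humidity=np.zeros(120, bool),
                          reagent_label="nitrosonium")
        with pytest.warns(UserWarning):
            products = attribute_products(table, 30.0)
        assert products == []

    def test_confounder_excluded_by_correlation(self, noisy_ramp):
        """A channel drifting independently of the spike is rejected even
        though it passes the rise threshold."""
        cfg, table = noisy_ramp
        corrected = correct_transmission(table,
                                         default_transmission_curve())
        products = attribute_products(corrected, cfg.schedule.spike_time)
        assert cfg.confounder_mz not in products
        assert 155.14 in products and 137.13 in products

    def test_spike_time_outside_run_rejected(self, noisy_ramp):
        _, table = noisy_ramp
        with pytest.raises(ValueError):
            attribute_products(table, 1e6)


class TestBranchingRatios:
    def test_single_product_is_always_100(self):
        cfg = RampConfig(seed=0, noise=False, compound_name="phenol",
                         reagent_label="nitrosonium",
                         branching=BranchingModel({144: {94.04: 100}}))
        table = simulate_ramp_run(cfg)
        analysis = analyze_ramp_run(table, cfg.schedule,
                                    default_transmission_curve())
        assert analysis.products == [94.04]
        assert np.allclose(analysis.branching.data.loc[94.04], 100.0)

    def test_noiseless_round_trip_below_point_one(self, noiseless_ramp):
        """Programmed branching recovered to < 0.1 percentage points."""
        cfg, table = noiseless_ramp
        analysis = analyze_ramp_run(table, cfg.schedule,
                                    default_transmission_curve(),
                                    compound="decanal")
        model = BranchingModel(DEFAULT_BRANCHING[("decanal",
                                                  "nitrosonium")])
        for td in analysis.branching.data.columns:
            programmed = model.fractions(td)
            got = analysis.branching.data[td]
            for mz, frac in programmed.items():
                expected = 100 * frac
                value = got.get(mz)
                if expected < 2.0:  # below the reporting threshold
                    continue
                assert value == pytest.approx(expected, abs=0.1), (td, mz)

    def test_column_sums_are_100(self, noiseless_ramp):
        cfg, table = noiseless_ramp
        analysis = analyze_ramp_run(table, cfg.schedule,
                                    default_transmission_curve())
        sums = analysis.branching.data.sum(axis=0, skipna=True)
        assert np.all(np.abs(sums - 100.0) <= 0.5)

    def test_invariant_to_global_rescaling(self, noiseless_ramp):
        cfg, table = noiseless_ramp
        slices = segment_ramp(table, cfg.schedule)
        products = [155.14, 137.13]
        base = branching_ratios(slices, products,
                                curve=default_transmission_curve())
        scaled_slices = []
        for sl in slices:
            scaled_slices.append(PeakTable(
                times=sl.times, channels=sl.channels, counts=sl.counts * 7.3,
                voltages=sl.voltages, humidity=sl.humidity,
                reagent_label=sl.reagent_label))
        scaled = branching_ratios(scaled_slices, products,
                                  curve=default_transmission_curve())
        pd.testing.assert_frame_equal(base.data, scaled.data)

    def test_equal_products_under_flat_transmission_split_evenly(self):
        table = PeakTable(times=np.arange(60.0),
                          channels=np.array([83.09, 101.10]),
                          counts=np.full((60, 2), 500.0),
                          voltages=np.full(60, 350.0),
                          humidity=np.zeros(60, bool),
                          reagent_label="nitrosonium",
                          transmission_corrected=True)
        out = branching_ratios([table], [83.09, 101.10])
        assert np.allclose(out.data.to_numpy(), 50.0)

    def test_empty_product_set_rejected(self, noiseless_ramp):
        cfg, table = noiseless_ramp
        slices = segment_ramp(table, cfg.schedule)
        with pytest.raises(ValueError):
            branching_ratios(slices, [])

    def test_percentages_bounded(self):
        with pytest.raises(ValueError):
            BranchingTable("x", "nitrosonium",
                           pd.DataFrame({84: [120.0]}, index=[101.1]))


class TestHumidityShift:
    def test_identical_tables_give_zero(self, noiseless_ramp):
        cfg, table = noiseless_ramp
        analysis = analyze_ramp_run(table, cfg.schedule,
                                    default_transmission_curve())
        deltas = humidity_shift(analysis.branching, analysis.branching)
        assert np.allclose(deltas.to_numpy(), 0.0)

    def test_programmed_nine_point_shift_recovered(self):
        """Humid -> dry switch at 84 Td moves 9 points into the fragment."""
        humid_anchors = {84: {71.07: 92, 43.05: 8}}
        dry_anchors = {84: {71.07: 83, 43.05: 17}}
        schedule = RampSchedule((350,), step_duration=120.0)
        tables = {}
        for label, anchors, humid in (("humid", humid_anchors, True),
                                      ("dry", dry_anchors, False)):
            cfg = RampConfig(seed=21, compound_name="butanal",
                             reagent_label="nitrosonium",
                             branching=BranchingModel(anchors),
                             schedule=schedule, humid=humid)
            table = simulate_ramp_run(cfg)
            analysis = analyze_ramp_run(table, schedule,
                                        default_transmission_curve())
            tables[label] = analysis.branching
        deltas = humidity_shift(tables["humid"], tables["dry"])
        assert deltas.loc[43.05, 84] == pytest.approx(9.0, abs=1.0)
        assert deltas.loc[71.07, 84] == pytest.approx(-9.0, abs=1.0)
        # shares are normalized: deltas cancel within each column
        assert np.allclose(deltas.sum(axis=0), 0.0, atol=1e-9)

    def test_mismatched_structure_rejected(self, noiseless_ramp):
        cfg, table = noiseless_ramp
        analysis = analyze_ramp_run(table, cfg.schedule,
                                    default_transmission_curve())
        other = BranchingTable("x", "nitrosonium",
                               pd.DataFrame({84: [100.0]}, index=[101.1]))
        with pytest.raises(ValueError):
            humidity_shift(analysis.branching, other)
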