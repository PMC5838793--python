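"""Peak-table dialect round trips and transmission-curve behavior."""

import numpy as np
import pytest

from ptrkit.kinetics import HYDRONIUM
from ptrkit.library import TRANSMISSION_REFERENCE_COMPOUNDS
from ptrkit.peaktable import (PeakTable, PeakTableParseError,
                              TransmissionCurve, build_transmission,
                              correct_transmission, read_peaktable,
                              read_transmission, write_peaktable,
                              write_transmission)
from ptrkit.synthetic import (CalibrationMixConfig, analyte_rates,
                              default_transmission_curve,
                              simulate_calibration_mix)


def small_table(**overrides):
    kwargs = dict(
        times=np.array([0.0, 1.0, 2.0]),
        channels=np.array([21.02, 59.05, 137.13]),
        counts=np.array([[10.0, 5.0, 1.5], [11.0, 6.0, 0.0],
                         [12.0, 7.0, 2.5]]),
        voltages=np.array([600.0, 600.0, 600.0]),
        humidity=np.array([True, True, False]),
        reagent_label="hydronium")
    kwargs.update(overrides)
    return PeakTable(**kwargs)


class TestDialect:
    def test_round_trip_identity(self, tmp_path):
        table = small_table(metadata={"note": "fixture"})
        path = tmp_path / "run.tsv"
        write_peaktable(table, path)
        back = read_peaktable(path)
        np.testing.assert_allclose(back.times, table.times)
        np.testing.assert_allclose(back.channels, table.channels)
        np.testing.assert_allclose(back.counts, table.counts)
        np.testing.assert_allclose(back.voltages, table.voltages)
        np.testing.assert_array_equal(back.humidity, table.humidity)
        assert back.reagent_label == table.reagent_label
        assert back.metadata["note"] == "fixture"
        # writing again produces the identical file
        path2 = tmp_path / "run2.tsv"
        write_peaktable(back, path2)
        assert path.read_text() == path2.read_text()

    def test_negative_count_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#columns\ttime_s\tvoltage_V\thumidity\t59.05\n"
                        "0\t600\t1\t5.0\n1\t600\t1\t-2.0\n")
        with pytest.raises(PeakTableParseError) as err:
            read_peaktable(path)
        assert err.value.line == 3

    def test_non_monotone_time_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#columns\ttime_s\tvoltage_V\thumidity\t59.05\n"
                        "1\t600\t1\t5.0\n0\t600\t1\t2.0\n")
        with pytest.raises(PeakTableParseError):
            read_peaktable(path)

    def test_row_width_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#columns\ttime_s\tvoltage_V\thumidity\t59.05\n"
                        "0\t600\t1\t5.0\t9.0\n")
        with pytest.raises(PeakTableParseError):
            read_peaktable(path)

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            small_table(counts=np.full((3, 3), -1.0))
        with pytest.raises(ValueError):
            small_table(channels=np.array([59.05, 21.02, 137.13]))


class TestTransmissionCurve:
    def test_spline_passes_through_knots_exactly(self):
        curve = default_transmission_curve()
        np.testing.assert_allclose(curve(curve.knot_mz),
                                   curve.knot_transmission, rtol=1e-12)

    def test_natural_boundary_conditions(self):
        curve = default_transmission_curve()
        second = curve._spline.derivative(2)
        assert second(curve.knot_mz[0]) == pytest.approx(0.0, abs=1e-10)
        assert second(curve.knot_mz[-1]) == pytest.approx(0.0, abs=1e-10)

    def test_clamped_outside_knot_range(self):
        curve = default_transmission_curve()
        assert curve(5.0) == pytest.approx(curve.knot_transmission[0])
        assert curve(500.0) == pytest.approx(curve.knot_transmission[-1])

    def test_requires_three_knots(self):
        with pytest.raises(ValueError):
            TransmissionCurve(np.array([50.0, 100.0]), np.array([0.5, 1.0]))

    def test_serialization_round_trip(self, tmp_path):
        curve = default_transmission_curve()
        path = tmp_path / "curve.tsv"
        write_transmission(curve, path)
        back = read_transmission(path)
        np.testing.assert_allclose(back.knot_mz, curve.knot_mz)
        np.testing.assert_allclose(back.knot_transmission,
                                   curve.knot_transmission, atol=1e-6)


class TestCorrectTransmission:
    def test_flat_curve_is_identity(self):
        table = small_table()
        flat = TransmissionCurve(np.array([10.0, 100.0, 200.0]),
                                 np.array([1.0, 1.0, 1.0]))
        out = correct_transmission(table, flat)
        np.testing.assert_allclose(out.counts, table.counts)

    def test_half_transmission_doubles_counts(self):
        table = small_table()
        half = TransmissionCurve(np.array([10.0, 100.0, 200.0]),
                                 np.array([0.5, 0.5, 0.5]))
        out = correct_transmission(table, half)
        np.testing.assert_allclose(out.counts, table.counts * 2)

    def test_double_correction_guarded(self):
        table = small_table()
        flat = TransmissionCurve(np.array([10.0, 100.0, 200.0]),
                                 np.array([1.0, 1.0, 1.0]))
        out = correct_transmission(table, flat)
        with pytest.raises(ValueError):
            correct_transmission(out, flat)

    def test_distortion_round_trip(self):
        """Applying then correcting the same curve restores the truth."""
        table = small_table()
        curve = default_transmission_curve()
        distorted = PeakTable(
            times=table.times, channels=table.channels,
            counts=table.counts * curve(table.channels)[None, :],
            voltages=table.voltages, humidity=table.humidity)
        out = correct_transmission(distorted, curve)
        np.testing.assert_allclose(out.counts, table.counts, rtol=1e-12)


def reference_rates(table, library):
    cond = table.conditions()
    refs = {}
    for name in TRANSMISSION_REFERENCE_COMPOUNDS:
        entry = library[name]
        mz = entry.product_channels["hydronium"][0]
        k, _ = analyte_rates(entry.params, HYDRONIUM, cond)
        refs[mz] = k
    return refs


class TestBuildTransmission:
    def test_recovers_programmed_curve_at_knots(self, library):
        table = simulate_calibration_mix(CalibrationMixConfig(seed=3))
        curve = build_transmission(table, 100.0, reference_rates(table,
                                                                 library),
                                   HYDRONIUM)
        truth = default_transmission_curve()(curve.knot_mz)
        truth = truth / truth.max()
        np.testing.assert_allclose(curve.knot_transmission, truth, rtol=0.05)

    def test_noiseless_recovery_is_exact(self, library):
        table = simulate_calibration_mix(CalibrationMixConfig(seed=0,
                                                              noise=False))
        curve = build_transmission(table, 100.0, reference_rates(table,
                                                                 library),
                                   HYDRONIUM)
        truth = default_transmission_curve()(curve.knot_mz)
        truth = truth / truth.max()
        np.testing.assert_allclose(curve.knot_transmission, truth,
                                   rtol=1e-10)

    def test_flat_instrument_gives_flat_curve(self, library):
        flat = TransmissionCurve(np.array([10.0, 100.0, 250.0]),
                                 np.array([1.0, 1.0, 1.0]))
        table = simulate_calibration_mix(
            CalibrationMixConfig(seed=0, noise=False, transmission=flat))
        curve = build_transmission(table, 100.0, reference_rates(table,
                                                                 library),
                                   HYDRONIUM)
        np.testing.assert_allclose(curve.knot_transmission, 1.0, rtol=1e-10)

    def test_too_few_references_rejected(self, library):
        table = simulate_calibration_mix(CalibrationMixConfig(seed=0,
                                                              noise=False))
        refs = dict(list(reference_rates(table, library).items())[:2])
        with pytest.raises(ValueError):
            build_transmission(table, 100.0, refs, HYDRONIUM)
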