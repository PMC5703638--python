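import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from cstetquant.calibration import (
    DensityEstimate,
    IntensityCalibration,
    ThresholdSet,
    density_fraction,
    equivalent_concentration,
    estimate_background,
    extrapolate_tcp_intensity,
    run_table3,
    tcp_formula_weight,
)

RATIOS = {"rrna_water": 2.29, "ribosome_water": 1.57, "tcp_water": 6.06}


class TestEstimateBackground:
    def test_rna_peak_pairing(self):
        """(5.3 - x)/(16 - x) = 2.29 solves to x = 24.3."""
        assert estimate_background(5.3, 16.0, 2.29) == pytest.approx(24.3, abs=0.05)

    def test_ribosome_inclusive_pairing(self):
        assert estimate_background(7.5, 16.0, 1.57) == pytest.approx(30.9, abs=0.05)

    def test_limit_large_ratio_approaches_water(self):
        x = estimate_background(15.0, 16.0, 1e6)
        assert 16.0 < x < 16.001

    def test_exactly_solves_the_ratio_equation(self):
        x = estimate_background(5.3, 16.0, 2.29)
        assert (5.3 - x) / (16.0 - x) == pytest.approx(2.29, rel=1e-12)

    def test_rejects_ratio_at_most_one(self):
        with pytest.raises(ValueError):
            estimate_background(5.3, 16.0, 1.0)

    def test_rejects_reference_above_water(self):
        with pytest.raises(ValueError):
            estimate_background(17.0, 16.0, 2.29)


class TestExtrapolateTcp:
    def test_primary_background(self):
        assert extrapolate_tcp_intensity(24.3, 16.0, 6.06) == pytest.approx(
            -26.0, abs=0.05
        )

    def test_parenthetical_background(self):
        assert extrapolate_tcp_intensity(30.9, 16.0, 6.06) == pytest.approx(
            -59.4, abs=0.05
        )

    def test_unit_ratio_returns_water(self):
        assert extrapolate_tcp_intensity(24.3, 16.0, 1.0) == 16.0

    def test_rejects_polarity_violation(self):
        with pytest.raises(ValueError):
            extrapolate_tcp_intensity(10.0, 16.0, 6.06)


@pytest.fixture
def primary_calibration(measured_thresholds):
    return IntensityCalibration.from_thresholds(
        measured_thresholds, RATIOS["rrna_water"], RATIOS["tcp_water"], "rna_peak"
    )


class TestDensityFraction:
    def test_granule_peak(self, primary_calibration):
        est = density_fraction(0.3, primary_calibration)
        assert est.ratio_to_water == pytest.approx(2.89, abs=0.005)
        assert est.fraction_of_tcp == pytest.approx(0.48, abs=0.005)

    def test_granule_inclusive(self, primary_calibration):
        est = density_fraction(3.0, primary_calibration)
        assert est.ratio_to_water == pytest.approx(2.57, abs=0.005)

    def test_background_maps_to_zero(self, primary_calibration):
        est = density_fraction(primary_calibration.background_x, primary_calibration)
        assert est.fraction_of_tcp == 0.0
        assert est.ratio_to_water == 0.0

    def test_tcp_intensity_maps_to_one(self, primary_calibration):
        est = density_fraction(primary_calibration.tcp_intensity, primary_calibration)
        assert est.fraction_of_tcp == pytest.approx(1.0, rel=1e-12)

    def test_water_fraction_is_inverse_tcp_ratio(self, primary_calibration):
        est = density_fraction(
            primary_calibration.water_intensity, primary_calibration
        )
        assert est.fraction_of_tcp == pytest.approx(
            1.0 / primary_calibration.tcp_water_ratio, rel=1e-12
        )

    def test_reference_recovers_predicted_ratio(self, measured_thresholds):
        """Calibrating on a reference then reading it back returns the ratio."""
        calib = IntensityCalibration.from_thresholds(
            measured_thresholds, 2.29, 6.06, "rna_peak"
        )
        est = density_fraction(measured_thresholds.ribosome_peak, calib)
        assert est.ratio_to_water == pytest.approx(2.29, rel=1e-12)
        assert est.fraction_of_tcp == pytest.approx(2.29 / 6.06, rel=1e-12)

    def test_strictly_decreasing_in_intensity(self, primary_calibration):
        fractions = [
            density_fraction(i, primary_calibration).fraction_of_tcp
            for i in (-10.0, 0.0, 5.0, 16.0, 24.0)
        ]
        assert all(a > b for a, b in zip(fractions, fractions[1:]))

    def test_intensity_above_background_is_flagged(self, primary_calibration):
        with pytest.raises(ValueError, match="negative density"):
            density_fraction(primary_calibration.background_x + 1.0,
                             primary_calibration)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        offset=st.floats(-50.0, 50.0),
        intensity=st.floats(-20.0, 16.0),
    )
    def test_affine_intensity_scale_invariance(self, scale, offset, intensity):
        """Density fractions are invariant under affine intensity remapping."""
        ts = ThresholdSet(0.3, 3.0, 5.3, 7.5, 16.0)
        calib = IntensityCalibration.from_thresholds(ts, 2.29, 6.06)
        mapped = ThresholdSet(
            *(scale * v + offset for v in dataclasses.astuple(ts))
        )
        calib2 = IntensityCalibration.from_thresholds(mapped, 2.29, 6.06)
        a = density_fraction(intensity, calib)
        b = density_fraction(scale * intensity + offset, calib2)
        assert b.fraction_of_tcp == pytest.approx(a.fraction_of_tcp, rel=1e-9,
                                                  abs=1e-12)
        assert b.ratio_to_water == pytest.approx(a.ratio_to_water, rel=1e-9,
                                                 abs=1e-12)


class TestEquivalentConcentration:
    def _estimate(self, fraction):
        mass = fraction * 3.14
        return DensityEstimate(fraction, 0.0, mass, mass / tcp_formula_weight())

    def test_calcium_at_one_fifth_fill(self):
        conc = equivalent_concentration(self._estimate(0.31), 0.20)
        assert conc["calcium_molar"] == pytest.approx(1.9, abs=0.05)

    def test_zero_volume_fraction(self):
        conc = equivalent_concentration(self._estimate(0.31), 0.0)
        assert conc == {"formula_molar": 0.0, "calcium_molar": 0.0,
                        "phosphate_molar": 0.0}

    def test_intragranule_molarity(self):
        # 0.31 * 3.14 / 310.17 * 1000 = 3.138 mol/L inside a granule
        conc = equivalent_concentration(self._estimate(0.31), 1.0)
        assert conc["formula_molar"] == pytest.approx(3.138, abs=0.005)

    def test_stoichiometric_multipliers(self):
        conc = equivalent_concentration(self._estimate(0.4), 0.1)
        assert conc["calcium_molar"] == pytest.approx(3 * conc["formula_molar"])
        assert conc["phosphate_molar"] == pytest.approx(2 * conc["formula_molar"])

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            equivalent_concentration(self._estimate(0.31), 1.2)


class TestRunTable3:
    EXPECTED_GRID = {
        # (ratio_to_water, ratio_to_tcp) for (primary, parenthetical)
        "granule_peak": ("2.89", "2.05", "0.48", "0.34"),
        "granule_inclusive": ("2.57", "1.87", "0.42", "0.31"),
        "ribosome_peak": ("2.29", "1.72", "0.38", "0.28"),
        "ribosome_inclusive": ("2.02", "1.57", "0.33", "0.26"),
        "water": ("1.00", "1.00", "0.17", "0.17"),
    }

    def test_grid_matches_reference_cells(self, measured_thresholds):
        rep = run_table3(measured_thresholds, RATIOS)
        fmt = rep["formatted"]
        for row, (rw_p, rw_q, rt_p, rt_q) in self.EXPECTED_GRID.items():
            assert fmt.loc[row, "ratio_to_water_primary"] == rw_p
            assert fmt.loc[row, "ratio_to_water_parenthetical"] == rw_q
            assert fmt.loc[row, "ratio_to_tcp_primary"] == rt_p
            assert fmt.loc[row, "ratio_to_tcp_parenthetical"] == rt_q

    def test_background_and_tcp_rows(self, measured_thresholds):
        fmt = run_table3(measured_thresholds, RATIOS)["formatted"]
        assert fmt.loc["background", "threshold_primary"] == "24.3"
        assert fmt.loc["background", "threshold_parenthetical"] == "30.9"
        assert fmt.loc["tcp", "threshold_primary"] == "-26.0"
        assert fmt.loc["tcp", "threshold_parenthetical"] == "-59.4"

    def test_water_tcp_ratio_unrounded_value(self, measured_thresholds):
        grid = run_table3(measured_thresholds, RATIOS)["grid"]
        assert grid.loc["water", "ratio_to_tcp_primary"] == pytest.approx(
            0.165, abs=0.001
        )

    def test_default_ratios_come_from_reference_tables(self, measured_thresholds):
        rep = run_table3(measured_thresholds)
        assert rep["ratios"] == RATIOS

    def test_degenerate_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSet(5.0, 5.0, 5.0, 5.0, 5.0)
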