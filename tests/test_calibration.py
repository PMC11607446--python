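"""VSMOW normalization, atom-percent conversion and internal-standard
quantification."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaporsip.calibration import (
    apply_calibration,
    atom_percent_to_delta,
    correct_fame_methyl_h,
    delta_to_atom_percent,
    fit_calibration,
    quantify_fa_carbon,
)
from vaporsip.errors import DegenerateFitError, DomainError, QuantificationError
from vaporsip.types import CalibrationModel, DeltaMeasurement, R_VSMOW_2H


def _std(compound, measured, known, idx=0):
    return DeltaMeasurement(
        compound=compound, delta_raw=measured, run_index=idx,
        is_standard=True, known_delta=known,
    )


class TestFitCalibration:
    def test_exact_standards_give_identity(self):
        cal = fit_calibration([_std("USGS70", -183.0, -183.0), _std("USGS72", 384.0, 384.0)])
        assert cal.slope == pytest.approx(1.0, abs=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)

    def test_two_point_line_solved_by_hand(self):
        # known {-183, 384} measured {-193, 374}: slope 1, intercept +10
        cal = fit_calibration([_std("USGS70", -193.0, -183.0), _std("USGS72", 374.0, 384.0)])
        assert cal.slope == pytest.approx(1.0, rel=1e-12)
        assert cal.intercept == pytest.approx(10.0, rel=1e-12)
        assert cal.drift_per_index == 0.0

    def test_single_standard_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_calibration([_std("USGS70", -183.0, -183.0)])

    def test_identical_measured_values_are_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_calibration([_std("a", 5.0, -183.0), _std("b", 5.0, 384.0)])

    def test_drift_estimated_from_repeated_standards(self):
        # true relation: measured drifts up 0.5 permil per run position
        stds = []
        for name, known in (("USGS70", -183.0), ("USGS72", 384.0)):
            for idx in (0, 10, 20):
                stds.append(_std(name, known + 0.5 * idx, known, idx))
        cal = fit_calibration(stds)
        assert cal.slope == pytest.approx(1.0, rel=1e-9)
        assert cal.drift_per_index == pytest.approx(0.5, rel=1e-9)
        # standards reproduce their known values through the fitted model
        for s in stds:
            assert apply_calibration(s, cal) == pytest.approx(s.known_delta, abs=1e-9)

    def test_standards_reproduced_within_residual_sd(self):
        rng = np.random.default_rng(42)
        stds = []
        for name, known in (("USGS70", -183.0), ("USGS72", 384.0), ("mix", 100.0)):
            for idx in range(0, 30, 6):
                measured = 0.98 * known - 12.0 + rng.normal(0, 3.0)
                stds.append(_std(name, measured, known, idx))
        cal = fit_calibration(stds)
        recovered = np.array([apply_calibration(s, cal) for s in stds])
        known = np.array([s.known_delta for s in stds])
        # noise scale matches bracketing-standard reproducibility (~4 permil)
        assert np.abs(recovered - known).max() <= 3.0 * max(cal.residual_sd, 1e-9)


class TestApplyCalibration:
    def test_identity_model_passes_through(self):
        cal = CalibrationModel(slope=1.0, intercept=0.0)
        m = DeltaMeasurement(compound="16:0", delta_raw=123.4)
        assert apply_calibration(m, cal) == 123.4

    def test_hand_arithmetic_offset(self):
        cal = CalibrationModel(slope=1.0, intercept=10.0)
        m = DeltaMeasurement(compound="16:0", delta_raw=-193.0)
        assert apply_calibration(m, cal) == pytest.approx(-183.0)

    def test_drift_correction_hand_arithmetic(self):
        cal = CalibrationModel(slope=1.0, intercept=0.0, drift_per_index=0.5)
        m = DeltaMeasurement(compound="16:0", delta_raw=50.0, run_index=10)
        assert apply_calibration(m, cal) == pytest.approx(45.0)

    def test_order_preserving_in_delta_raw(self):
        cal = CalibrationModel(slope=0.97, intercept=-27.0, drift_per_index=0.2)
        vals = [
            apply_calibration(DeltaMeasurement(compound="x", delta_raw=d, run_index=5), cal)
            for d in (-200.0, 0.0, 300.0)
        ]
        assert vals == sorted(vals)


class TestAtomPercentConversion:
    @pytest.mark.parametrize(
        "delta, expected",
        [(0.0, 0.015573574260073253), (1000.0, 0.03114229855115535)],
    )
    def test_vsmow_anchor_values(self, delta, expected):
        assert delta_to_atom_percent(delta, R_VSMOW_2H) == pytest.approx(expected, rel=1e-9)

    def test_domain_error_below_minus_1000(self):
        with pytest.raises(DomainError):
            delta_to_atom_percent(-1000.0, R_VSMOW_2H)

    @given(st.floats(min_value=-999.0, max_value=60000.0))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_and_bounds(self, delta):
        at = delta_to_atom_percent(delta, R_VSMOW_2H)
        assert 0 < at < 100
        back = atom_percent_to_delta(at, R_VSMOW_2H)
        assert back == pytest.approx(delta, rel=1e-10, abs=1e-10)

    def test_strictly_monotone(self):
        deltas = np.linspace(-900, 50000, 400)
        ats = delta_to_atom_percent(deltas, R_VSMOW_2H)
        assert np.all(np.diff(ats) > 0)


class TestQuantifyFaCarbon:
    def test_equal_area_equals_is_amount(self):
        out = quantify_fa_carbon({"16:0": 100.0, "19:0": 100.0}, 1000.0, 1.0)
        assert out["16:0"] == pytest.approx(1000.0)
        assert "19:0" not in out  # internal standard excluded downstream

    def test_hand_arithmetic(self):
        out = quantify_fa_carbon({"16:0": 250.0, "19:0": 500.0}, 1000.0, 0.8)
        assert out["16:0"] == pytest.approx(625.0, rel=1e-12)

    def test_zero_area_gives_zero(self):
        out = quantify_fa_carbon({"16:0": 0.0, "19:0": 500.0}, 1000.0, 1.0)
        assert out["16:0"] == 0.0

    def test_missing_internal_standard_raises(self):
        with pytest.raises(QuantificationError):
            quantify_fa_carbon({"16:0": 250.0}, 1000.0, 1.0)


class TestFameMethylCorrection:
    def test_identical_pools_change_nothing(self):
        assert correct_fame_methyl_h(0.2, 0.2, 31) == pytest.approx(0.2, rel=1e-12)

    def test_hydrogen_mass_balance_round_trip(self):
        # mix a known fatty acid with methanol hydrogen and recover it
        at_fa, at_meoh, n_fa = 0.207, 0.0150, 31
        at_fame = (at_fa * n_fa + at_meoh * 3) / (n_fa + 3)
        assert correct_fame_methyl_h(at_fame, at_meoh, n_fa) == pytest.approx(
            at_fa, rel=1e-12
        )

    def test_unphysical_correction_rejected(self):
        with pytest.raises(DomainError):
            correct_fame_methyl_h(0.016, 50.0, 31)
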