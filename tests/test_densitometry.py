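"""Normalization, calibration fitting, LOD, inverse prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agtlc.densitometry import (
    CalibrationCurve,
    estimate_blank_sd,
    fit_calibration,
    limit_of_detection,
    normalize_saturation,
    predict_amount,
)
from agtlc.pipeline import _measure_calibration_plate
from agtlc.synthetic_plate import (
    OLIVETOL,
    OLIVETOL_AMOUNT_UG,
    PRESETS,
    default_layout,
    make_calibration_series,
    render_plate,
)

pos = st.floats(min_value=1e-3, max_value=1.0, allow_nan=False)


class TestNormalize:
    @pytest.mark.parametrize(
        "analyte, ref, expected",
        [(0.40, 0.40, 1.0), (0.0, 0.40, 0.0), (0.30, 0.40, 0.75)],
    )
    def test_known_ratios(self, analyte, ref, expected):
        assert normalize_saturation(analyte, ref) == pytest.approx(expected)

    def test_zero_reference_signals_unusable_plate(self):
        with pytest.raises(ValueError):
            normalize_saturation(0.3, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(a=pos, r=pos, c=st.floats(min_value=0.1, max_value=10))
    def test_scale_invariance(self, a, r, c):
        """Rescaling both saturations (the shared development gain the
        olivetol reference exists to remove) leaves the ratio fixed."""
        assert normalize_saturation(a * c, r * c) == pytest.approx(
            normalize_saturation(a, r), rel=1e-9
        )


class TestFitCalibration:
    AMOUNTS = (0.2, 0.5, 0.8, 1.0, 2.0)

    def test_perfect_line_recovered_exactly(self):
        pts = [(a, 0.5 * a + 0.1) for a in self.AMOUNTS]
        curve = fit_calibration(pts, "THC")
        assert curve.slope == pytest.approx(0.5)
        assert curve.intercept == pytest.approx(0.1)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.amount_range == (0.2, 2.0)
        assert curve.valid

    def test_noisy_replicates_recover_slope(self):
        """3 replicates per level with sd-0.02 noise: slope within 10%."""
        rng = np.random.default_rng(42)
        pts = [
            (a, 0.5 * a + 0.1 + rng.normal(0, 0.02))
            for a in self.AMOUNTS
            for _ in range(3)
        ]
        curve = fit_calibration(pts, "THC")
        assert curve.slope == pytest.approx(0.5, rel=0.10)

    def test_flat_response_flagged_invalid(self):
        curve = fit_calibration([(a, 0.3) for a in self.AMOUNTS], "x")
        assert curve.slope == 0.0 and not curve.valid

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(0.2, 0.1), (0.5, 0.2)], "x")

    def test_duplicate_amounts_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 0.1), (1.0, 0.2), (1.0, 0.3)], "x")

    def test_serialization_round_trip(self):
        curve = fit_calibration([(a, 0.5 * a) for a in self.AMOUNTS], "THC")
        curve = curve.with_lod(0.005)
        back = CalibrationCurve.from_dict(curve.to_dict())
        assert back == curve


class TestLod:
    def test_zero_blank_gives_zero(self):
        assert limit_of_detection(0.0, 1.5) == 0.0

    def test_hand_computed_value(self):
        # 3 * 0.005 / 1.5 = 0.01 ug = 10 ng
        assert limit_of_detection(0.005, 1.5) == pytest.approx(10.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            limit_of_detection(0.01, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(sd=pos, slope=st.floats(min_value=0.01, max_value=10), c=st.floats(min_value=0.1, max_value=10))
    def test_linear_in_blank_sd_inverse_in_slope(self, sd, slope, c):
        assert limit_of_detection(c * sd, slope) == pytest.approx(
            c * limit_of_detection(sd, slope), rel=1e-9
        )
        assert limit_of_detection(sd, c * slope) == pytest.approx(
            limit_of_detection(sd, slope) / c, rel=1e-9
        )


class TestPredict:
    CURVE = CalibrationCurve("THC", 0.5, 0.1, 0.99, (0.2, 2.0), lod_ng=20.0)

    def test_round_trip_is_exact(self):
        for a in (0.2, 0.77, 2.0):
            pred = predict_amount(self.CURVE, 0.5 * a + 0.1)
            assert pred.amount_ug == pytest.approx(a)
            assert not pred.flagged

    def test_signal_at_intercept_flagged(self):
        pred = predict_amount(self.CURVE, 0.1)
        assert pred.amount_ug == pytest.approx(0.0)
        assert pred.below_lod and pred.out_of_range
        assert pred.display() == "<LOD"

    def test_above_range_flagged_but_estimated(self):
        pred = predict_amount(self.CURVE, 0.5 * 3.0 + 0.1)
        assert pred.out_of_range and not pred.below_lod
        assert pred.amount_ug == pytest.approx(3.0)

    def test_invalid_curve_rejected(self):
        bad = CalibrationCurve("x", 0.0, 0.3, 0.0, (0.2, 2.0))
        with pytest.raises(ValueError):
            predict_amount(bad, 0.5)


class TestGeneratorRecovery:
    """Measured normalized signals against the generator's own response
    model: the normalized slope is sat_slope / olivetol saturation."""

    def test_noiseless_fit_recovers_generator_slope(self):
        lay = default_layout(6)
        amounts = [0.2, 0.5, 0.8, 1.0, 2.0]
        specs = make_calibration_series(PRESETS["THC"], amounts, lay)
        img, _ = render_plate(
            lay, specs, noise_sd=0, spot_cv=0, plate_cv=0, dev_cv=0, seed=0
        )
        pts = _measure_calibration_plate(img, lay, tuple(amounts), 0.03, 20)
        curve = fit_calibration(pts, "THC")
        expected = PRESETS["THC"].sat_slope / (
            OLIVETOL.sat_slope * OLIVETOL_AMOUNT_UG
        )
        assert curve.slope == pytest.approx(expected, rel=0.02)
        assert curve.r_squared > 0.999

    def test_noisy_inverse_prediction_error(self, calibration):
        """Median absolute relative error of recovered amounts stays
        below 15% across the linear range at default noise."""
        from agtlc.pipeline import RenderSettings

        lay = default_layout(6)
        amounts = [0.2, 0.5, 0.8, 1.0, 2.0]
        curve = calibration.curves["THC"]
        errors = []
        settings_ = RenderSettings()
        for seed in range(6):
            specs = make_calibration_series(PRESETS["THC"], amounts, lay)
            img, _ = settings_.render(lay, specs, seed)
            pts = _measure_calibration_plate(img, lay, tuple(amounts), 0.03, 20)
            for a, sig in pts:
                pred = predict_amount(curve, sig)
                errors.append(abs(pred.amount_ug - a) / a)
        assert np.median(errors) <= 0.15


def test_blank_sd_measured_from_clean_patches(layout4, default_settings):
    img, _ = default_settings.render(layout4, [], 3)
    sd = estimate_blank_sd(img, layout4, reference_sat=0.15)
    assert 0 < sd < 0.05
    with pytest.raises(ValueError):
        estimate_blank_sd(img, layout4, reference_sat=0.0)
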