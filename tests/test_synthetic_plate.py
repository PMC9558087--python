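"""Synthetic plate generator: geometry, determinism, blending, series
builders."""

import numpy as np
import pytest

from agtlc.colorspace import hsb_planes
from agtlc.synthetic_plate import (
    OLIVETOL,
    PRESETS,
    AnalyteProfile,
    PlateLayout,
    SpotSpec,
    default_layout,
    make_calibration_series,
    make_mixture_series,
    render_plate,
    six_standard_specs,
)


class TestPlateLayout:
    def test_default_dimensions(self):
        lay = default_layout(4)
        assert lay.plate_width == 40.0
        assert lay.plate_height == 70.0
        assert lay.origin_y == 10.0 and lay.front_y == 60.0
        assert lay.ag_zone_top_y == pytest.approx(23.3)
        assert lay.reference_lane == 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(origin_y=0.0),  # origin on the edge
            dict(front_y=80.0),  # front above plate top
            dict(ag_zone_top_y=5.0),  # Ag zone below origin
            dict(pixel_size=0.0),
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        base = dict(
            plate_width=40, plate_height=70, origin_y=10, front_y=60,
            ag_zone_top_y=23.3, lanes=(8, 16), reference_lane=1, pixel_size=0.2,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            PlateLayout(**base)

    def test_spot_y_interpolates_between_origin_and_front(self):
        lay = default_layout(2)
        assert lay.spot_y(0.0) == 10.0
        assert lay.spot_y(1.0) == 60.0
        assert lay.spot_y(0.70) == pytest.approx(45.0)


class TestRenderPlate:
    def test_same_seed_is_bit_identical(self, layout4):
        specs = [SpotSpec(PRESETS["THC"], 0, 1.0)]
        img1, _ = render_plate(layout4, specs, seed=11)
        img2, _ = render_plate(layout4, specs, seed=11)
        assert np.array_equal(img1, img2)

    def test_different_seed_differs(self, layout4):
        specs = [SpotSpec(PRESETS["THC"], 0, 1.0)]
        img1, _ = render_plate(layout4, specs, seed=11)
        img2, _ = render_plate(layout4, specs, seed=12)
        assert not np.array_equal(img1, img2)

    def test_blank_plate_has_zero_saturation(self, layout4):
        img, truth = render_plate(
            layout4, [], noise_sd=0, spot_cv=0, plate_cv=0, dev_cv=0, seed=0
        )
        _, sat, _ = hsb_planes(img)
        assert sat.max() == 0.0
        assert truth.spots == []

    def test_ground_truth_centroid_from_rf(self):
        """Rf 0.70 between origin 10 and front 60 lands at y = 45 mm."""
        lay = default_layout(2)
        img, truth = render_plate(
            lay, [SpotSpec(PRESETS["THC"], 0, 1.0)], noise_sd=0, spot_cv=0,
            plate_cv=0, dev_cv=0, seed=0,
        )
        assert truth.spots[0].y_mm == pytest.approx(45.0)
        assert truth.spots[0].rf == pytest.approx(0.70)

    def test_ground_truth_one_record_per_spot(self, layout7):
        specs = six_standard_specs(1.0)
        _, truth = render_plate(layout7, specs, seed=3)
        assert len(truth.spots) == len(specs)
        assert [r.lane for r in truth.spots] == [s.lane for s in specs]
        assert [r.amount_ug for r in truth.spots] == [s.amount for s in specs]

    def test_unmigrated_spot_sits_on_origin_line(self, layout4):
        spec = SpotSpec(OLIVETOL, 3, 0.1, migrated=False)
        _, truth = render_plate(layout4, [spec], seed=0)
        assert truth.spots[0].y_mm == layout4.origin_y
        assert truth.spots[0].rf is None

    def test_background_is_flat_without_noise_or_tint(self, layout4):
        img, _ = render_plate(
            layout4, [SpotSpec(PRESETS["THC"], 0, 1.0)],
            noise_sd=0, spot_cv=0, plate_cv=0, dev_cv=0, ag_tint=0, seed=0,
        )
        # all pixels > 4 sigma away from the spot are identical
        lay = layout4
        xs, ys = lay.x_coords_mm(), lay.y_coords_mm()
        d2 = (ys[:, None] - 45.0) ** 2 + (xs[None, :] - lay.lanes[0]) ** 2
        bg = img[d2 > (4 * 1.1 + 0.5) ** 2]
        assert (bg == bg[0]).all()

    def test_mean_saturation_nondecreasing_in_amount(self, layout4):
        """More analyte -> more color, up to the saturation ceiling."""
        means = []
        for amount in (0.1, 0.5, 1.0, 2.0, 5.0):
            img, _ = render_plate(
                layout4, [SpotSpec(PRESETS["THC"], 1, amount)],
                noise_sd=0, spot_cv=0, plate_cv=0, dev_cv=0, seed=0,
            )
            _, sat, _ = hsb_planes(img)
            means.append(sat[sat > 0].mean())
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_peak_saturation_capped_at_sat_max(self, layout4):
        img, _ = render_plate(
            layout4, [SpotSpec(PRESETS["THC"], 1, 50.0)],
            noise_sd=0, spot_cv=0, plate_cv=0, dev_cv=0, seed=0,
        )
        _, sat, _ = hsb_planes(img)
        assert sat.max() <= PRESETS["THC"].sat_max + 1 / 255

    def test_ag_tint_darkens_lower_zone_only(self, layout4):
        img, _ = render_plate(
            layout4, [], noise_sd=0, spot_cv=0, plate_cv=0, dev_cv=0,
            ag_tint=0.2, seed=0,
        )
        _, _, bright = hsb_planes(img)
        ys = layout4.y_coords_mm()
        below = bright[ys <= layout4.ag_zone_top_y, :].mean()
        above = bright[ys > layout4.ag_zone_top_y, :].mean()
        assert below < above

    def test_lane_out_of_range_rejected(self, layout4):
        with pytest.raises(ValueError):
            render_plate(layout4, [SpotSpec(PRESETS["THC"], 9, 1.0)], seed=0)

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            SpotSpec(PRESETS["THC"], 0, -0.5)


class TestSeriesBuilders:
    def test_calibration_series_counts(self, layout7):
        specs = make_calibration_series(
            PRESETS["THC"], [0.2, 0.5, 0.8, 1.0, 2.0], layout7
        )
        assert len(specs) == 6  # five amounts + olivetol reference
        assert specs[-1].analyte is OLIVETOL
        assert specs[-1].lane == layout7.reference_lane
        assert not specs[-1].migrated

    def test_empty_amounts_gives_reference_only(self, layout4):
        specs = make_calibration_series(PRESETS["THC"], [], layout4)
        assert len(specs) == 1 and specs[0].analyte is OLIVETOL

    def test_single_amount_on_two_lane_layout(self):
        lay = default_layout(2)
        specs = make_calibration_series(PRESETS["THC"], [1.0], lay)
        assert len(specs) == 2

    def test_too_many_amounts_rejected(self, layout4):
        with pytest.raises(ValueError):
            make_calibration_series(PRESETS["THC"], [0.1] * 5, layout4)

    @pytest.mark.parametrize(
        "ratio, want",
        [(0.0, [("THC", 1.0)]), (1.0, [("CBN", 1.0)]),
         (0.6, [("THC", 0.4), ("CBN", 0.6)])],
    )
    def test_mixture_amounts(self, ratio, want):
        specs = make_mixture_series([ratio], 1.0)
        got = sorted((s.analyte.name, s.amount) for s in specs)
        assert got == sorted(
            [(n, pytest.approx(a)) for n, a in want],
            key=lambda t: t[0],
        )

    def test_mixture_pairs_share_a_lane(self):
        specs = make_mixture_series([0.3, 0.5], 1.0)
        lanes = {}
        for s in specs:
            lanes.setdefault(s.lane, []).append(s.analyte.name)
        assert lanes == {0: ["THC", "CBN"], 1: ["THC", "CBN"]}

    def test_mixture_ratio_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_mixture_series([1.2], 1.0)


def test_presets_carry_published_rf_values():
    """Retention factors on unmodified silica match the reported ones."""
    assert PRESETS["THC"].rf_unmodified == 0.55
    assert PRESETS["CBD"].rf_unmodified == 0.60
    assert PRESETS["THCA"].rf_unmodified == 0.29
    assert PRESETS["CBDA"].rf_unmodified == 0.34


def test_cbn_response_is_seventy_percent_of_thc():
    assert PRESETS["CBN"].sat_slope == pytest.approx(0.7 * PRESETS["THC"].sat_slope)


def test_analyte_profile_validation():
    with pytest.raises(ValueError):
        AnalyteProfile("x", 1.5, 0.5, 10, 0.3)  # Rf > 1
    with pytest.raises(ValueError):
        AnalyteProfile("x", 0.5, 0.5, 400, 0.3)  # hue out of range
    with pytest.raises(ValueError):
        AnalyteProfile("x", 0.5, 0.5, 10, -1.0)  # negative slope
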