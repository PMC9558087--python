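"""Synthetic Ag(I)-TLC plate images with known ground truth.

Real plates carry three zones along the migration axis: an Ag(I)
retention zone (lower part of the plate, impregnated with AgNO3) that
immobilizes 1,5-diene cannabinoids (CBD analogues), a detection zone
where single-olefin cannabinoids (THC analogues) migrate to their Rf,
and a reference lane whose spots are loaded but never eluted.  After
spraying with Fast Blue BB, each cannabinoid spot develops an
analyte-specific hue whose saturation grows with the loaded amount.

The generator renders that phenomenology directly in HSB space:

* a near-white silica background (saturation 0, brightness ~0.96),
  optionally darkened in the Ag zone and tilted by an illumination
  gradient;
* each spot is a 2-D Gaussian chroma footprint centred at
  ``y = origin_y + Rf * (front_y - origin_y)`` in its lane, with peak
  saturation ``min(sat_slope * amount, sat_max)``;
* co-located spots blend by chroma-weighted circular hue mixing with
  additive saturation capped at ``sat_max``;
* variability enters at four levels: a plate-wide multiplicative
  color-development gain (``plate_cv``, the component the olivetol
  reference normalization exists to remove); a smooth development
  field (``dev_cv``/``dev_corr_mm``) modelling spatially correlated
  spray/development unevenness -- nearby spots develop alike while the
  distant reference spot decorrelates, so normalization removes it only
  partially; independent per-spot jitter (``spot_cv``); and per-pixel
  Gaussian saturation noise (``noise_sd``).

It is a colorimetric emulation, not a physical model: Rf values, hues
and saturation responses are inputs taken from the preset table, never
predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .colorspace import image_from_hsb

__all__ = [
    "PlateLayout",
    "AnalyteProfile",
    "SpotSpec",
    "SpotRecord",
    "GroundTruth",
    "PRESETS",
    "OLIVETOL",
    "THC_ANALOGUES",
    "CBD_ANALOGUES",
    "STANDARD_ORDER",
    "default_layout",
    "render_plate",
    "make_calibration_series",
    "make_mixture_series",
    "six_standard_specs",
]

# Footprint truncation radius in units of sigma.  Outside this radius a
# spot contributes exactly zero, so noiseless backgrounds are bit-flat.
_TRUNCATE_SIGMA = 4.0


@dataclass(frozen=True)
class PlateLayout:
    """Plate geometry in mm; origin of the y axis at the plate bottom.

    ``origin_y`` is the sample loading line, ``front_y`` the mobile-phase
    boundary line, ``ag_zone_top_y`` the upper edge of the Ag(I)
    retention zone.  ``lanes`` holds lane-centre x positions; spots in
    ``reference_lane`` are loaded but never migrated.
    """

    plate_width: float
    plate_height: float
    origin_y: float
    front_y: float
    ag_zone_top_y: float
    lanes: tuple[float, ...]
    reference_lane: int
    pixel_size: float

    def __post_init__(self) -> None:
        if not 0 < self.origin_y < self.ag_zone_top_y < self.front_y <= self.plate_height:
            raise ValueError(
                "layout requires 0 < origin_y < ag_zone_top_y < front_y <= plate_height"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if len(self.lanes) == 0:
            raise ValueError("layout needs at least one lane")
        if not all(0 < x < self.plate_width for x in self.lanes):
            raise ValueError("lane centers must lie inside (0, plate_width)")
        if not 0 <= self.reference_lane < len(self.lanes):
            raise ValueError("reference_lane out of range")
        object.__setattr__(self, "lanes", tuple(float(x) for x in self.lanes))

    @property
    def n_lanes(self) -> int:
        return len(self.lanes)

    @property
    def shape_px(self) -> tuple[int, int]:
        """Raster (rows, cols).  Row 0 is the top of the plate."""
        return (
            int(round(self.plate_height / self.pixel_size)),
            int(round(self.plate_width / self.pixel_size)),
        )

    def x_coords_mm(self) -> np.ndarray:
        """x of each pixel-column centre."""
        n = self.shape_px[1]
        return (np.arange(n) + 0.5) * self.pixel_size

    def y_coords_mm(self) -> np.ndarray:
        """y of each pixel-row centre (row 0 = top of plate)."""
        n = self.shape_px[0]
        return self.plate_height - (np.arange(n) + 0.5) * self.pixel_size

    def spot_y(self, rf: float) -> float:
        """Migration-axis position of a spot at retention factor ``rf``."""
        return self.origin_y + rf * (self.front_y - self.origin_y)


@dataclass(frozen=True)
class AnalyteProfile:
    """Chromatographic and chromogenic behaviour of one analyte.

    ``rf_unmodified`` / ``rf_ag`` are retention factors on plain silica
    and on the Ag(I) plate; ``hue_deg`` is the hue of the Fast Blue BB
    azo product; ``sat_slope`` the peak-saturation response per ug
    loaded; ``sat_max`` the saturation ceiling; ``sigma_mm`` the Gaussian
    spot radius.
    """

    name: str
    rf_unmodified: float
    rf_ag: float
    hue_deg: float
    sat_slope: float
    sat_max: float = 0.85
    sigma_mm: float = 1.1

    def __post_init__(self) -> None:
        for rf in (self.rf_unmodified, self.rf_ag):
            if not 0.0 <= rf <= 1.0:
                raise ValueError(f"Rf {rf} outside [0, 1]")
        if not 0.0 <= self.hue_deg < 360.0:
            raise ValueError("hue_deg outside [0, 360)")
        if self.sat_slope <= 0:
            raise ValueError("sat_slope must be positive")
        if not 0.0 < self.sat_max <= 1.0:
            raise ValueError("sat_max outside (0, 1]")
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be positive")

    def rf(self, plate_type: str) -> float:
        if plate_type == "ag":
            return self.rf_ag
        if plate_type == "unmodified":
            return self.rf_unmodified
        raise ValueError(f"unknown plate_type {plate_type!r}")


# Published Rf values on unmodified silica: THC 0.55, CBD 0.60,
# THCA 0.29, CBDA 0.34.  On the Ag(I) plate THC analogues migrate into
# the detection zone (THC and CBN co-migrate; THCA lower) while CBD
# analogues stay pinned near the origin inside the retention zone.
# Hues: the FBBB product of THC/THCA is orange, of CBN purple.  The CBN
# saturation response is ~70% of the THC response at equal amount.
PRESETS: dict[str, AnalyteProfile] = {
    "THC": AnalyteProfile("THC", 0.55, 0.70, 25.0, 0.35),
    "CBN": AnalyteProfile("CBN", 0.45, 0.70, 285.0, 0.245),
    "THCA": AnalyteProfile("THCA", 0.29, 0.50, 25.0, 0.35),
    "CBD": AnalyteProfile("CBD", 0.60, 0.08, 15.0, 0.35),
    "CBG": AnalyteProfile("CBG", 0.40, 0.05, 15.0, 0.35),
    "CBDA": AnalyteProfile("CBDA", 0.34, 0.03, 15.0, 0.35),
    "olivetol": AnalyteProfile("olivetol", 0.90, 0.90, 345.0, 4.0),
}

OLIVETOL = PRESETS["olivetol"]
OLIVETOL_AMOUNT_UG = 0.10  # 1.0 uL of 0.10 ug/uL reference solution

THC_ANALOGUES = ("THC", "CBN", "THCA")
CBD_ANALOGUES = ("CBD", "CBG", "CBDA")
# Left-to-right lane order of the six-standard comparison plate.
STANDARD_ORDER = ("THC", "CBD", "CBN", "CBG", "THCA", "CBDA")


@dataclass(frozen=True)
class SpotSpec:
    """One spot to render: analyte, lane, loaded amount, migration flag."""

    analyte: AnalyteProfile
    lane: int
    amount: float
    migrated: bool = True

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be nonnegative")


@dataclass(frozen=True)
class SpotRecord:
    """Ground-truth record of one rendered spot."""

    lane: int
    analyte: str
    amount_ug: float
    x_mm: float
    y_mm: float
    rf: float | None  # None for un-migrated (reference-lane) spots


@dataclass
class GroundTruth:
    """Sidecar truth for a rendered plate: per-spot records, optional
    per-sample potency truth, and the render seed."""

    spots: list[SpotRecord]
    sample: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def to_records(self) -> list[dict]:
        return [vars(s).copy() for s in self.spots]


def default_layout(
    n_lanes: int = 4,
    *,
    lane_pitch: float = 8.0,
    margin: float = 8.0,
    pixel_size: float = 0.2,
    plate_height: float = 70.0,
    origin_y: float = 10.0,
    front_y: float = 60.0,
    ag_zone_top_y: float = 23.3,
    reference_lane: int | None = None,
) -> PlateLayout:
    """Default plate: 70 mm tall strip, origin 10 mm, front 60 mm, Ag
    zone covering the lower third, lanes on an 8 mm pitch (a 4-lane
    strip is 40 mm wide).  The last lane is the un-eluted reference
    lane unless stated otherwise."""
    if n_lanes < 1:
        raise ValueError("need at least one lane")
    width = 2 * margin + (n_lanes - 1) * lane_pitch
    lanes = tuple(margin + i * lane_pitch for i in range(n_lanes))
    return PlateLayout(
        plate_width=width,
        plate_height=plate_height,
        origin_y=origin_y,
        front_y=front_y,
        ag_zone_top_y=ag_zone_top_y,
        lanes=lanes,
        reference_lane=n_lanes - 1 if reference_lane is None else reference_lane,
        pixel_size=pixel_size,
    )


def _development_field(
    centers: list[tuple[float, float]],
    dev_cv: float,
    corr_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multiplicative development gains at spot centres.

    Gaussian process with mean 1, SD ``dev_cv`` and squared-exponential
    covariance exp(-d^2 / (2 corr_mm^2)): co-located spots share their
    gain exactly, and correlation decays smoothly with distance.
    Negative draws (only conceivable at unrealistic dev_cv) clip to 0.
    """
    n = len(centers)
    if n == 0 or dev_cv == 0:
        return np.ones(n)
    pts = np.asarray(centers)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    cov = dev_cv**2 * np.exp(-d2 / (2.0 * corr_mm**2))
    cov[np.diag_indices(n)] += 1e-12  # nugget for co-located spots
    z = rng.standard_normal(n)
    return np.clip(1.0 + np.linalg.cholesky(cov) @ z, 0.0, None)


def render_plate(
    layout: PlateLayout,
    spots: list[SpotSpec],
    *,
    noise_sd: float = 0.015,
    illum_gradient: float = 0.0,
    ag_tint: float = 0.08,
    spot_cv: float = 0.03,
    plate_cv: float = 0.05,
    dev_cv: float = 0.05,
    dev_corr_mm: float = 35.0,
    plate_type: str = "ag",
    seed: int,
    background_bright: float = 0.96,
    background_hue: float = 45.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a plate to an 8-bit RGB array plus its ground truth.

    Parameters
    ----------
    noise_sd
        SD of per-pixel Gaussian noise added to the saturation plane.
    illum_gradient
        Fractional top-to-bottom linear brightness ramp (0 = flat).
    ag_tint
        Fractional brightness reduction inside the Ag(I) zone.
    spot_cv
        Relative SD of independent per-spot development jitter (e.g.
        loading error); never removed by normalization.
    plate_cv
        Relative SD of one plate-wide multiplicative development gain,
        shared by every spot including the olivetol reference, hence
        removed by normalization.
    dev_cv, dev_corr_mm
        SD and correlation length of a smooth multiplicative
        development field (squared-exponential covariance) sampled at
        spot centres: co-located and nearby spots share their gain,
        spots far from the reference decorrelate from it.  This is the
        dominant contribution to replicate spread after normalization.
    plate_type
        ``"ag"`` (use ``rf_ag``) or ``"unmodified"`` (use
        ``rf_unmodified``).
    seed
        Seeds all randomness; identical calls are bit-identical.
    """
    if min(noise_sd, spot_cv, plate_cv, dev_cv) < 0:
        raise ValueError("noise parameters must be nonnegative")
    rng = np.random.default_rng(seed)
    plate_gain = max(1.0 + rng.normal(0.0, plate_cv), 0.0) if plate_cv > 0 else 1.0
    centers = []
    for spec in spots:
        if not 0 <= spec.lane < layout.n_lanes:
            raise ValueError(f"lane {spec.lane} out of range for layout")
        rf = spec.analyte.rf(plate_type) if spec.migrated else None
        centers.append(
            (layout.lanes[spec.lane],
             layout.spot_y(rf) if spec.migrated else layout.origin_y)
        )
    dev_field = _development_field(centers, dev_cv, dev_corr_mm, rng)
    n_rows, n_cols = layout.shape_px
    xs = layout.x_coords_mm()
    ys = layout.y_coords_mm()

    # Chroma accumulators: vector hue mixing weighted by saturation.
    acc_u = np.zeros((n_rows, n_cols))
    acc_v = np.zeros((n_rows, n_cols))
    acc_s = np.zeros((n_rows, n_cols))
    cap = np.zeros((n_rows, n_cols))

    truth = GroundTruth(spots=[], seed=seed)
    for k, spec in enumerate(spots):
        prof = spec.analyte
        rf = prof.rf(plate_type) if spec.migrated else None
        x0, y0 = centers[k]
        jitter = 1.0 + rng.normal(0.0, spot_cv) if spot_cv > 0 else 1.0
        gain = plate_gain * dev_field[k] * max(jitter, 0.0)
        peak = min(prof.sat_slope * spec.amount * gain, prof.sat_max)
        truth.spots.append(
            SpotRecord(spec.lane, prof.name, spec.amount, x0, y0, rf)
        )
        if peak <= 0:
            continue
        r_trunc = _TRUNCATE_SIGMA * prof.sigma_mm
        cols = np.flatnonzero(np.abs(xs - x0) <= r_trunc)
        rows = np.flatnonzero(np.abs(ys - y0) <= r_trunc)
        if cols.size == 0 or rows.size == 0:
            continue
        dx = xs[cols] - x0
        dy = ys[rows] - y0
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        foot = d2 <= r_trunc**2
        s = np.where(foot, peak * np.exp(-d2 / (2.0 * prof.sigma_mm**2)), 0.0)
        h = math.radians(prof.hue_deg)
        sub = np.ix_(rows, cols)
        acc_u[sub] += s * math.cos(h)
        acc_v[sub] += s * math.sin(h)
        acc_s[sub] += s
        cap[sub] = np.maximum(cap[sub], np.where(foot, prof.sat_max, 0.0))

    sat = np.where(acc_s > 0, np.minimum(acc_s, np.where(cap > 0, cap, 1.0)), 0.0)
    hue = np.where(
        acc_s > 0, np.degrees(np.arctan2(acc_v, acc_u)) % 360.0, background_hue
    )

    bright = np.full((n_rows, n_cols), background_bright)
    if illum_gradient:
        ramp = 1.0 + illum_gradient * (ys / layout.plate_height - 0.5)
        bright *= ramp[:, None]
    if ag_tint:
        bright[ys <= layout.ag_zone_top_y, :] *= 1.0 - ag_tint

    if noise_sd > 0:
        sat = sat + rng.normal(0.0, noise_sd, size=sat.shape)
    sat = np.clip(sat, 0.0, 1.0)
    bright = np.clip(bright, 0.0, 1.0)

    return image_from_hsb(hue, sat, bright), truth


def make_calibration_series(
    analyte: AnalyteProfile,
    amounts: list[float],
    layout: PlateLayout,
    *,
    reference_amount: float = OLIVETOL_AMOUNT_UG,
) -> list[SpotSpec]:
    """Specs for a calibration plate: one spot per amount in consecutive
    sample lanes plus the un-migrated olivetol spot in the reference
    lane."""
    if any(a < 0 for a in amounts):
        raise ValueError("amounts must be nonnegative")
    sample_lanes = [i for i in range(layout.n_lanes) if i != layout.reference_lane]
    if len(amounts) > len(sample_lanes):
        raise ValueError(
            f"{len(amounts)} amounts but only {len(sample_lanes)} sample lanes"
        )
    specs = [
        SpotSpec(analyte, lane, amount)
        for lane, amount in zip(sample_lanes, amounts)
    ]
    specs.append(
        SpotSpec(OLIVETOL, layout.reference_lane, reference_amount, migrated=False)
    )
    return specs


def make_mixture_series(
    ratios: list[float],
    total_amount: float,
    *,
    start_lane: int = 0,
    thc: AnalyteProfile | None = None,
    cbn: AnalyteProfile | None = None,
) -> list[SpotSpec]:
    """Specs for a THC+CBN mixture series at constant total amount.

    For each CBN/(THC+CBN) ratio ``r`` the lane receives a co-located
    pair: CBN ``r * total`` and THC ``(1 - r) * total`` (zero-amount
    members are omitted, so the pure end points are single spots).
    """
    thc = thc or PRESETS["THC"]
    cbn = cbn or PRESETS["CBN"]
    if total_amount < 0:
        raise ValueError("total_amount must be nonnegative")
    specs: list[SpotSpec] = []
    for i, r in enumerate(ratios):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"ratio {r} outside [0, 1]")
        lane = start_lane + i
        if (1.0 - r) * total_amount > 0:
            specs.append(SpotSpec(thc, lane, (1.0 - r) * total_amount))
        if r * total_amount > 0:
            specs.append(SpotSpec(cbn, lane, r * total_amount))
    return specs


def six_standard_specs(amount: float = 1.0, *, start_lane: int = 0) -> list[SpotSpec]:
    """The six-standard comparison plate (THC, CBD, CBN, CBG, THCA,
    CBDA left to right), one lane per standard."""
    return [
        SpotSpec(PRESETS[name], start_lane + i, amount)
        for i, name in enumerate(STANDARD_ORDER)
    ]
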