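"""Olivetol-normalized densitometry: calibration curves, LOD, and
inverse prediction of loaded amounts.

Olivetol (5-pentylbenzene-1,3-diol) also couples with Fast Blue BB, so
the saturation of its fixed-amount reference spot tracks plate-to-plate
variation in color development and image acquisition.  Dividing every
analyte saturation by the reference saturation removes that shared
factor; the normalized signal is what gets calibrated.

Calibration is an ordinary least-squares line over the linear range
(0.2-2 ug by default).  It is not forced through the origin, and
replicate plates contribute individual points rather than averages.
LOD follows the 3-sigma convention: 3 x SD(blank) / slope, reported in
ng for a 1 uL load.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sstats

from .colorspace import hsb_planes
from .segmentation import Spot
from .synthetic_plate import PlateLayout

__all__ = [
    "NormalizedSignal",
    "CalibrationCurve",
    "PredictedAmount",
    "normalize_saturation",
    "fit_calibration",
    "limit_of_detection",
    "predict_amount",
    "estimate_blank_sd",
]


@dataclass(frozen=True)
class NormalizedSignal:
    """Analyte saturation divided by the olivetol reference saturation."""

    value: float
    analyte_spot: Spot | None = None
    reference_spot: Spot | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("normalized signal must be nonnegative")


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line signal = slope * amount + intercept over ``amount_range``.

    ``lod_ng`` is 3 x SD(blank)/slope in ng; None until the blank SD of
    an analyzed plate is available.
    """

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    amount_range: tuple[float, float]
    lod_ng: float | None = None

    @property
    def valid(self) -> bool:
        return self.slope > 0

    def with_lod(self, blank_sd: float) -> "CalibrationCurve":
        return CalibrationCurve(
            self.analyte, self.slope, self.intercept, self.r_squared,
            self.amount_range, limit_of_detection(blank_sd, self.slope),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amount_range"] = list(self.amount_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        d = dict(d)
        d["amount_range"] = tuple(d["amount_range"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class PredictedAmount:
    """Inverse prediction with its quality flags.

    ``amount_ug`` is the point estimate even when flagged; callers
    render below-LOD results as "<LOD" rather than zero.
    """

    amount_ug: float
    below_lod: bool
    out_of_range: bool

    @property
    def flagged(self) -> bool:
        return self.below_lod or self.out_of_range

    def display(self) -> str:
        if self.below_lod:
            return "<LOD"
        text = f"{self.amount_ug:.3f}"
        return text + (" (out of range)" if self.out_of_range else "")


def normalize_saturation(analyte_sat: float, reference_sat: float) -> float:
    """Ratio of analyte to reference saturation.

    A zero reference saturation means the olivetol spot did not develop
    and the plate is unusable.
    """
    if reference_sat <= 0:
        raise ValueError("reference saturation must be positive (unusable plate)")
    if analyte_sat < 0:
        raise ValueError("analyte saturation must be nonnegative")
    return analyte_sat / reference_sat


def fit_calibration(
    points: list[tuple[float, float]], analyte: str = ""
) -> CalibrationCurve:
    """OLS calibration line through (amount ug, normalized signal) points.

    Requires at least three distinct amounts.  A nonpositive fitted
    slope yields a curve flagged invalid (``valid`` is False).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    amounts = np.asarray([p[0] for p in points], dtype=float)
    signals = np.asarray([p[1] for p in points], dtype=float)
    if len(np.unique(amounts)) < 3:
        raise ValueError("need at least 3 distinct amounts")
    if np.ptp(amounts) == 0:
        raise ValueError("zero variance in amounts")
    if np.allclose(signals, signals[0]):
        # Flat response: slope 0, invalid curve.
        return CalibrationCurve(
            analyte, 0.0, float(signals[0]), 0.0,
            (float(amounts.min()), float(amounts.max())),
        )
    fit = sstats.linregress(amounts, signals)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        amount_range=(float(amounts.min()), float(amounts.max())),
    )


def limit_of_detection(blank_sd: float, slope: float) -> float:
    """LOD (ng) = 3 x SD(blank) / slope, with slope per ug."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if blank_sd < 0:
        raise ValueError("blank SD must be nonnegative")
    return 3.0 * blank_sd / slope * 1000.0


def predict_amount(
    curve: CalibrationCurve, signal: "NormalizedSignal | float"
) -> PredictedAmount:
    """Invert the calibration line for one normalized signal.

    Flags the estimate when it falls below the LOD or outside the
    fitted amount range; the point estimate is retained either way.
    """
    if not curve.valid:
        raise ValueError(f"calibration curve for {curve.analyte!r} is invalid")
    value = signal.value if isinstance(signal, NormalizedSignal) else float(signal)
    amount = (value - curve.intercept) / curve.slope
    lo, hi = curve.amount_range
    below_lod = curve.lod_ng is not None and amount * 1000.0 < curve.lod_ng
    out_of_range = not (lo <= amount <= hi)
    return PredictedAmount(float(amount), below_lod, out_of_range)


def estimate_blank_sd(
    image: np.ndarray,
    layout: PlateLayout,
    reference_sat: float,
    *,
    spots: list[Spot] | None = None,
    patch_mm: float = 3.0,
    min_patches: int = 10,
) -> float:
    """SD of the normalized background saturation of a plate.

    The detection zone is tiled with ``patch_mm`` square patches;
    patches overlapping any detected spot footprint are dropped; each
    remaining patch contributes its mean saturation divided by the
    reference saturation.  At least ``min_patches`` clean patches are
    required.
    """
    if reference_sat <= 0:
        raise ValueError("reference saturation must be positive")
    _, sat, _ = hsb_planes(image)
    ys = layout.y_coords_mm()
    xs = layout.x_coords_mm()
    occupied = np.zeros(sat.shape, dtype=bool)
    if spots:
        for s in spots:
            occupied |= s.pixel_region
    side = max(2, int(round(patch_mm / layout.pixel_size)))
    det_rows = np.flatnonzero(ys > layout.ag_zone_top_y)
    r_start, r_stop = det_rows.min(), det_rows.max() + 1
    values = []
    for r in range(r_start, r_stop - side + 1, side):
        for c in range(0, len(xs) - side + 1, side):
            block_occ = occupied[r : r + side, c : c + side]
            if block_occ.any():
                continue
            values.append(sat[r : r + side, c : c + side].mean())
    if len(values) < min_patches:
        raise ValueError(
            f"only {len(values)} clean background patches, need {min_patches}"
        )
    return float(np.std(np.asarray(values) / reference_sat, ddof=1))
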