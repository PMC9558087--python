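"""Spot detection, zone assignment, and the chromatographic metrics
Rf (retention factor) and Rs (resolution).

Coordinate convention: physical coordinates are in mm with the origin
at the plate's bottom-left and y increasing with migration; raster
pixel (0, 0) is the top-left corner.  ``PlateLayout.y_coords_mm``
performs the flip, so all downstream math stays in plate coordinates.

The migration axis is partitioned into exactly two zones by
``ag_zone_top_y`` (Ag retention at or below, detection above); the
reference zone is the un-eluted reference lane, assigned by lane rather
than by y because its spots sit at the loading line regardless of
height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.measure import label, regionprops

from .colorspace import ColorStats, hsb_planes, mean_color
from .synthetic_plate import PlateLayout

__all__ = [
    "Spot",
    "zone_for_y",
    "detect_spots",
    "retention_factor",
    "resolution",
    "find_reference_spot",
]

#: aperture radius (mm) for the densitometric signal readout
DEFAULT_APERTURE_MM = 2.4


@dataclass(frozen=True)
class Spot:
    """One detected blob with its color statistics and chromatography."""

    centroid_x: float
    centroid_y: float
    pixel_region: np.ndarray  # boolean mask, full image shape
    stats: ColorStats
    lane: int
    zone: str  # "detection" | "ag_retention" | "reference"
    rf: float | None
    width_mm: float  # 4-sigma width of the vertical saturation profile
    signal: float  # background-subtracted mean saturation in the aperture


def zone_for_y(y_mm: float, layout: PlateLayout) -> str:
    """Migration-axis zone of a y position: ``ag_retention`` at or below
    the Ag-zone boundary, ``detection`` above.  Exhaustive and disjoint."""
    return "ag_retention" if y_mm <= layout.ag_zone_top_y else "detection"


def _nearest_lane(x_mm: float, layout: PlateLayout) -> int:
    d = np.abs(np.asarray(layout.lanes) - x_mm)
    return int(np.argmin(d))  # argmin breaks ties toward the lower index


def _gaussian(y, amp, mu, sigma):
    return amp * np.exp(-((y - mu) ** 2) / (2.0 * sigma**2))


def _profile_width_mm(
    excess: np.ndarray, rows: np.ndarray, cols: np.ndarray, ys: np.ndarray, pixel_size: float
) -> float:
    """4-sigma width from a Gaussian fit of the vertical saturation
    profile, falling back to 4x the weighted SD if the fit fails."""
    r0, r1 = rows.min(), rows.max()
    margin = max(3, (r1 - r0) // 2)
    r0 = max(0, r0 - margin)
    r1 = min(excess.shape[0] - 1, r1 + margin)
    prof = excess[r0 : r1 + 1][:, np.unique(cols)].mean(axis=1)
    yy = ys[r0 : r1 + 1]
    w = np.clip(prof, 0.0, None)
    mu0 = float((w * yy).sum() / w.sum())
    sd0 = float(np.sqrt((w * (yy - mu0) ** 2).sum() / w.sum()))
    sd0 = max(sd0, pixel_size / 4.0)
    try:
        popt, _ = curve_fit(
            _gaussian, yy, prof, p0=(float(prof.max()), mu0, sd0), maxfev=2000
        )
        sigma = abs(float(popt[2]))
        if not np.isfinite(sigma) or sigma <= 0:
            raise RuntimeError
    except Exception:
        sigma = sd0
    return 4.0 * sigma


def detect_spots(
    image: np.ndarray,
    layout: PlateLayout,
    sat_threshold: float = 0.03,
    min_area_px: int = 20,
    *,
    aperture_mm: float = DEFAULT_APERTURE_MM,
) -> list[Spot]:
    """Detect colored spots on a plate image.

    Background saturation is estimated per pixel column as the column
    median (robust because spots occupy a small fraction of each lane).
    Pixels whose saturation exceeds background + ``sat_threshold`` are
    grouped by 8-connectivity; components below ``min_area_px`` are
    discarded.  Each component yields an intensity-weighted centroid,
    nearest-lane assignment, zone label, color statistics over the
    component mask, a Gaussian 4-sigma width, and the aperture signal
    used for quantification (mean background-subtracted saturation in a
    fixed disc around the centroid, which is proportional to the spot's
    peak saturation for a fixed spot shape).
    """
    if sat_threshold <= 0:
        raise ValueError("sat_threshold must be positive")
    if min_area_px <= 0:
        raise ValueError("min_area_px must be positive")
    n_rows, n_cols = layout.shape_px
    if image.shape[:2] != (n_rows, n_cols):
        raise ValueError("image shape does not match layout raster")

    _, sat, _ = hsb_planes(image)
    background = np.median(sat, axis=0)  # per-column
    excess = sat - background[None, :]
    mask = excess > sat_threshold
    labels = label(mask, connectivity=2)
    xs = layout.x_coords_mm()
    ys = layout.y_coords_mm()

    spots: list[Spot] = []
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        w = np.clip(excess[rows, cols], 0.0, None)
        if w.sum() <= 0:
            continue
        cx = float((w * xs[cols]).sum() / w.sum())
        cy = float((w * ys[rows]).sum() / w.sum())
        lane = _nearest_lane(cx, layout)
        zone = "reference" if lane == layout.reference_lane else zone_for_y(cy, layout)
        region_mask = labels == region.label
        stats = mean_color(image, region_mask)
        width = _profile_width_mm(excess, rows, cols, ys, layout.pixel_size)
        d2 = (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2
        aperture = d2 <= aperture_mm**2
        sig = float(np.clip(excess[aperture], 0.0, None).mean())
        rf = None
        spot = Spot(cx, cy, region_mask, stats, lane, zone, rf, width, sig)
        if zone != "reference":
            spot = Spot(
                cx, cy, region_mask, stats, lane, zone,
                retention_factor(spot, layout), width, sig,
            )
        spots.append(spot)
    spots.sort(key=lambda s: (s.lane, -s.centroid_y))
    return spots


def retention_factor(spot: Spot, layout: PlateLayout) -> float:
    """Rf = (centroid_y - origin_y) / (front_y - origin_y), clipped to
    [0, 1].  Reference-lane spots are never eluted and have no Rf."""
    if spot.zone == "reference":
        raise ValueError("reference-zone spots have no retention factor")
    rf = (spot.centroid_y - layout.origin_y) / (layout.front_y - layout.origin_y)
    return float(np.clip(rf, 0.0, 1.0))


def resolution(spot_a: Spot, spot_b: Spot) -> float:
    """Chromatographic resolution Rs = 2|d_b - d_a| / (w_a + w_b).

    Migration distances share the origin line, so the distance
    difference equals the centroid-y difference; widths are the
    4-sigma widths of the vertical profiles.  Symmetric in its
    arguments and invariant under rescaling all lengths.
    """
    wsum = spot_a.width_mm + spot_b.width_mm
    if wsum <= 0:
        raise ValueError("zero combined spot width")
    return float(2.0 * abs(spot_b.centroid_y - spot_a.centroid_y) / wsum)


def find_reference_spot(spots: list[Spot]) -> Spot | None:
    """The strongest spot in the reference lane, or None."""
    refs = [s for s in spots if s.zone == "reference"]
    if not refs:
        return None
    return max(refs, key=lambda s: s.signal)
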