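"""RGB <-> HSB conversion and region color statistics.

The quantification channel throughout this package is HSB *saturation*
(hexcone model: B = max/255, S = (max-min)/max), the same readout an
image-analysis tool such as ImageJ reports for a measured spot.  Array
conversions are delegated to :mod:`skimage.color`, which implements the
identical hexcone transform.

Conventions
-----------
* Hue is reported in degrees in ``[0, 360)``; saturation and brightness
  are dimensionless in ``[0, 1]``.
* Achromatic pixels (``r == g == b``) have undefined hue; it is reported
  as 0 deg and such pixels are excluded from circular hue means.
* Region statistics are computed per pixel and then averaged, not from
  the mean RGB triple: this mirrors measuring the mean S of a drawn
  region in an image tool, and the two differ for non-uniform regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

__all__ = [
    "ColorStats",
    "rgb_to_hsb",
    "hsb_to_rgb",
    "hsb_planes",
    "image_from_hsb",
    "mean_color",
]


@dataclass(frozen=True)
class ColorStats:
    """Per-region color summary (channel means, HSB means, pixel count)."""

    mean_r: float
    mean_g: float
    mean_b: float
    mean_hue: float  # degrees, circular mean over chromatic pixels
    mean_sat: float
    mean_bright: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("ColorStats requires at least one pixel")
        for name in ("mean_r", "mean_g", "mean_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v} outside [0, 255]")


def _check_channel(value: float, name: str) -> None:
    if not 0 <= value <= 255:
        raise ValueError(f"channel {name}={value} outside [0, 255]")


def rgb_to_hsb(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Convert one 8-bit RGB triple to (hue deg, saturation, brightness).

    Standard hexcone model: brightness = max/255, saturation =
    (max - min)/max (0 for black), hue from the dominant-channel sector.
    Achromatic inputs give hue 0.
    """
    _check_channel(r, "r")
    _check_channel(g, "g")
    _check_channel(b, "b")
    hsv = rgb2hsv(np.array([[[r, g, b]]], dtype=np.float64) / 255.0)[0, 0]
    return float(hsv[0] * 360.0), float(hsv[1]), float(hsv[2])


def hsb_to_rgb(hue: float, sat: float, bright: float) -> tuple[int, int, int]:
    """Convert (hue deg, saturation, brightness) to a rounded 8-bit triple."""
    if not 0.0 <= sat <= 1.0:
        raise ValueError(f"saturation {sat} outside [0, 1]")
    if not 0.0 <= bright <= 1.0:
        raise ValueError(f"brightness {bright} outside [0, 1]")
    hsv = np.array([[[float(hue) % 360.0 / 360.0, sat, bright]]])
    rgb = np.rint(hsv2rgb(hsv)[0, 0] * 255.0).astype(int)
    return int(rgb[0]), int(rgb[1]), int(rgb[2])


def hsb_planes(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HSB planes (hue deg, sat, bright) of an 8-bit RGB image array."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    hsv = rgb2hsv(np.asarray(image, dtype=np.float64) / 255.0)
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def image_from_hsb(hue: np.ndarray, sat: np.ndarray, bright: np.ndarray) -> np.ndarray:
    """Render HSB planes into an 8-bit RGB image (rounding at write time)."""
    hsv = np.stack(
        [np.asarray(hue, dtype=np.float64) % 360.0 / 360.0,
         np.clip(sat, 0.0, 1.0),
         np.clip(bright, 0.0, 1.0)],
        axis=-1,
    )
    return np.rint(hsv2rgb(hsv) * 255.0).astype(np.uint8)


def mean_color(image: np.ndarray, region: np.ndarray) -> ColorStats:
    """Color statistics of ``image`` over boolean pixel mask ``region``.

    Channel means are plain averages; S and B are averaged per pixel; hue
    uses the circular mean over chromatic (S > 0) pixels only.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != image.shape[:2]:
        raise ValueError("region mask shape does not match image")
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")
    px = np.asarray(image, dtype=np.float64)[region]
    hue, sat, bright = hsb_planes(image)
    h, s, v = hue[region], sat[region], bright[region]
    chromatic = s > 0
    if chromatic.any():
        rad = np.radians(h[chromatic])
        mean_hue = float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)
    else:
        mean_hue = 0.0
    return ColorStats(
        mean_r=float(px[:, 0].mean()),
        mean_g=float(px[:, 1].mean()),
        mean_b=float(px[:, 2].mean()),
        mean_hue=mean_hue,
        mean_sat=float(s.mean()),
        mean_bright=float(v.mean()),
        n_pixels=n,
    )
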