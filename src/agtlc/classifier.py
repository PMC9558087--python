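"""High-CBN detection from spot color (the R-B index).

THC and CBN co-migrate on the Ag(I) plate, but their Fast Blue BB
products differ in color: orange for THC, purple for CBN.  The relative
difference between the red and blue channels of the combined spot,

    raw = (mean_R - mean_B) / (mean_R + mean_B),

is therefore a proxy for the CBN/(THC+CBN) ratio.  It is normalized
against per-run pure-standard references to an index that is 1 for pure
THC and 0 for pure CBN, and an index -> fraction lookup (piecewise
linear, fitted on a rendered mixture series) estimates the CBN
fraction.  Samples above the 0.6 fraction threshold are quantified with
the CBN calibration curve, all others (including the exact boundary)
with the THC curve.

The index is monotone nonincreasing in the true CBN fraction but flat
near the pure-THC end (hues within the red sector give identical R-B
contrast), so low CBN fractions are not resolved individually; the
decision near 0.6, where the index is steep, is what matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import ColorStats

__all__ = [
    "CBN_FRACTION_THRESHOLD",
    "CbnIndex",
    "MixtureLookup",
    "rb_ratio",
    "cbn_index",
    "fit_mixture_lookup",
    "select_curve",
    "classify_spot",
]

#: CBN/(THC+CBN) fraction above which the CBN curve is appropriate
CBN_FRACTION_THRESHOLD = 0.6


@dataclass(frozen=True)
class CbnIndex:
    """Color classification of one THC/CBN spot."""

    raw_rb: float  # (R-B)/(R+B) in [-1, 1]
    index: float  # normalized: 1 = pure THC color, 0 = pure CBN color
    est_cbn_fraction: float
    high_cbn: bool  # est_cbn_fraction > 0.6 -> use the CBN curve

    @property
    def curve(self) -> str:
        return "CBN" if self.high_cbn else "THC"


@dataclass(frozen=True)
class MixtureLookup:
    """Per-run color references plus the index -> CBN-fraction map.

    ``index_grid``/``fraction_grid`` come from a rendered mixture
    series; the map is piecewise linear in the index, with duplicate
    index values (the flat low-CBN limb) collapsed to their mean
    fraction.
    """

    raw_thc_ref: float
    raw_cbn_ref: float
    index_grid: tuple[float, ...] = field(default_factory=tuple)
    fraction_grid: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.raw_thc_ref == self.raw_cbn_ref:
            raise ValueError("THC and CBN reference colors are identical")
        if len(self.index_grid) != len(self.fraction_grid):
            raise ValueError("index and fraction grids differ in length")

    @property
    def calibrated(self) -> bool:
        return len(self.index_grid) >= 2

    def fraction(self, index: float) -> float:
        if not self.calibrated:
            raise ValueError("mixture lookup is not calibrated")
        return float(np.interp(index, self.index_grid, self.fraction_grid))

    def to_dict(self) -> dict:
        return {
            "raw_thc_ref": self.raw_thc_ref,
            "raw_cbn_ref": self.raw_cbn_ref,
            "index_grid": list(self.index_grid),
            "fraction_grid": list(self.fraction_grid),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureLookup":
        return cls(
            raw_thc_ref=d["raw_thc_ref"],
            raw_cbn_ref=d["raw_cbn_ref"],
            index_grid=tuple(d["index_grid"]),
            fraction_grid=tuple(d["fraction_grid"]),
        )


def rb_ratio(stats: ColorStats) -> float:
    """Relative red-blue difference (mean_R - mean_B)/(mean_R + mean_B)."""
    total = stats.mean_r + stats.mean_b
    if total <= 0:
        raise ValueError("black spot: R + B is zero")
    return float((stats.mean_r - stats.mean_b) / total)


def cbn_index(raw: float, raw_thc_ref: float, raw_cbn_ref: float) -> float:
    """Normalize a raw R-B value between the pure-standard references:
    1 at the THC reference color, 0 at the CBN reference, clipped."""
    if raw_thc_ref == raw_cbn_ref:
        raise ValueError("reference values are identical")
    return float(np.clip((raw - raw_cbn_ref) / (raw_thc_ref - raw_cbn_ref), 0.0, 1.0))


def fit_mixture_lookup(
    raw_thc_ref: float,
    raw_cbn_ref: float,
    indices: list[float],
    fractions: list[float],
) -> MixtureLookup:
    """Build the index -> fraction lookup from a measured mixture series.

    Points are sorted by index; ties in the index (the unresolved
    low-CBN limb) are merged by averaging their true fractions, which
    keeps the interpolant single-valued without affecting the 0.6
    decision (the index is steep there).
    """
    if len(indices) != len(fractions) or len(indices) < 2:
        raise ValueError("need >= 2 (index, fraction) pairs")
    order = np.argsort(indices)
    idx = np.asarray(indices, dtype=float)[order]
    frac = np.asarray(fractions, dtype=float)[order]
    merged_i: list[float] = []
    merged_f: list[float] = []
    tol = 1e-9
    i = 0
    while i < len(idx):
        j = i
        while j + 1 < len(idx) and idx[j + 1] - idx[i] <= tol:
            j += 1
        merged_i.append(float(idx[i:j + 1].mean()))
        merged_f.append(float(frac[i:j + 1].mean()))
        i = j + 1
    if len(merged_i) < 2:
        raise ValueError("mixture series is colorimetrically degenerate")
    return MixtureLookup(
        raw_thc_ref, raw_cbn_ref, tuple(merged_i), tuple(merged_f)
    )


def select_curve(index: float, lookup: MixtureLookup) -> tuple[str, float]:
    """Choose the calibration curve for a THC/CBN spot.

    Returns ``("CBN", fraction)`` when the estimated CBN fraction
    exceeds 0.6, else ``("THC", fraction)``; the exact boundary belongs
    to the THC regime.
    """
    frac = lookup.fraction(index)
    return ("CBN" if frac > CBN_FRACTION_THRESHOLD else "THC"), frac


def classify_spot(stats: ColorStats, lookup: MixtureLookup) -> CbnIndex:
    """Full color classification of one detected spot."""
    raw = rb_ratio(stats)
    idx = cbn_index(raw, lookup.raw_thc_ref, lookup.raw_cbn_ref)
    curve, frac = select_curve(idx, lookup)
    return CbnIndex(raw, idx, frac, curve == "CBN")
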