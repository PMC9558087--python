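"""Potency arithmetic: mass percentages and total THC potential.

Total THC potential is a screening statistic that sums everything that
is, or can become, psychoactive THC-equivalent material:

    total THC potential (%) = 0.877 * %THCA + %(THC + CBN)

The 0.877 factor is the molecular-weight ratio MW(THC)/MW(THCA): on
decarboxylation THCA loses CO2, so only that fraction of its mass ends
up as THC.  CBN (the oxidative degradation product of THC) is counted
1:1 with THC even though its own psychoactive potency is ~10% of THC's
-- a deliberate screening overestimate that minimizes false negatives.
A potency-weighted variant is available but is not the default.

Percentages are of dry sample weight: a measured extract concentration
c (ug/mL) in extraction volume VOL (mL) from DW (mg) of material gives
c * VOL / (10 * DW) percent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ATOMIC_WEIGHTS",
    "SamplePrep",
    "PotencyResult",
    "molecular_weight",
    "decarboxylation_factor",
    "DECARB_FACTOR",
    "mass_percent",
    "total_thc_potential",
    "weighted_thc_potential",
    "spiked_percent",
    "MARIJUANA_THRESHOLD_PCT",
]

# IUPAC 2021 standard atomic weights (conventional values), enough for
# the cannabinoid and common small-molecule formulas handled here.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Na": 22.990,
    "K": 39.098,
}

#: dry-weight THC percentage above which material counts as marijuana
MARIJUANA_THRESHOLD_PCT = 0.3

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class SamplePrep:
    """Extraction bookkeeping for one sample.

    Defaults follow the standard workup: 100.0 mg dry material extracted
    into 300 uL (0.300 mL) of MeOH, 1.0 uL loaded per lane, no dilution.
    """

    extraction_volume_ml: float = 0.300
    dry_weight_mg: float = 100.0
    loaded_volume_ul: float = 1.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("extraction_volume_ml", "dry_weight_mg", "loaded_volume_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class PotencyResult:
    """Mass percentages (of dry weight) and the combined statistic."""

    pct_thca: float
    pct_thc_cbn: float
    total_thc_potential: float
    curve_used: str

    def __post_init__(self) -> None:
        if min(self.pct_thca, self.pct_thc_cbn, self.total_thc_potential) < 0:
            raise ValueError("percentages must be nonnegative")

    @property
    def above_marijuana_threshold(self) -> bool:
        return self.total_thc_potential > MARIJUANA_THRESHOLD_PCT


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparsable formula {formula!r}")
        pos = m.end()
        element, digits = m.group(1), m.group(2)
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"unparsable formula {formula!r}")
    return counts


def molecular_weight(formula: str) -> float:
    """Average molecular weight (g/mol) from standard atomic weights."""
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in _parse_formula(formula).items())


def decarboxylation_factor(neutral_formula: str, acid_formula: str) -> float:
    """MW(neutral)/MW(acid), rounded to 3 decimals.

    For THC (C21H30O2) over THCA (C22H30O4) this is 0.877, the mass
    fraction of the acid that survives decarboxylation.
    """
    return round(molecular_weight(neutral_formula) / molecular_weight(acid_formula), 3)


#: MW(THC)/MW(THCA) = MW(C21H30O2)/MW(C22H30O4)
DECARB_FACTOR = decarboxylation_factor("C21H30O2", "C22H30O4")


def mass_percent(conc_ug_per_ml: float, prep: SamplePrep) -> float:
    """Percent of dry weight for a measured extract concentration.

    percent = c (ug/mL) * dilution * VOL (mL) / (DW (mg) * 10), i.e.
    ug analyte over ug sample times 100.
    """
    if conc_ug_per_ml < 0:
        raise ValueError("concentration must be nonnegative")
    total_ug = conc_ug_per_ml * prep.dilution_factor * prep.extraction_volume_ml
    return total_ug / (prep.dry_weight_mg * 10.0)


def total_thc_potential(pct_thca: float, pct_thc_cbn: float) -> float:
    """0.877 * %THCA + %(THC+CBN), the screening potency statistic."""
    if pct_thca < 0 or pct_thc_cbn < 0:
        raise ValueError("percentages must be nonnegative")
    return DECARB_FACTOR * pct_thca + pct_thc_cbn


def weighted_thc_potential(
    pct_thca: float, pct_thc: float, pct_cbn: float, cbn_weight: float = 0.1
) -> float:
    """Potency-weighted variant discounting CBN to ``cbn_weight`` of
    THC.  Requires separately known THC and CBN percentages, which the
    co-migrating spot cannot provide; off the default reporting path."""
    if min(pct_thca, pct_thc, pct_cbn) < 0:
        raise ValueError("percentages must be nonnegative")
    return DECARB_FACTOR * pct_thca + pct_thc + cbn_weight * pct_cbn


def spiked_percent(
    conc_in_spike_ug_per_ml: float, spiked_volume_ml: float, dry_weight_mg: float
) -> float:
    """Ground-truth percent of dry weight contributed by a spiked
    volume of a stock of known concentration."""
    if dry_weight_mg <= 0:
        raise ValueError("dry weight must be positive")
    if conc_in_spike_ug_per_ml < 0 or spiked_volume_ml < 0:
        raise ValueError("inputs must be nonnegative")
    return conc_in_spike_ug_per_ml * spiked_volume_ml / (dry_weight_mg * 10.0)
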