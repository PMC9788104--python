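"""Back-of-envelope supplementation effort and cost arithmetic.

Translates a simulated supplementation rate (fraction of target reef area
added per year) into absolute areas and costs for a real reef system of a
given size: annual outplanting area, cumulative effort over a program
duration, and annual cost at a per-hectare restoration price.  Reef areas
are user inputs; the default price is the reported median for
propagate-and-transplant restoration (US$351,661 per hectare).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EffortQuery",
    "annual_input_area",
    "total_effort",
    "annual_cost",
    "genetic_variance_from_heritability",
    "round_sig",
    "DEFAULT_COST_PER_HA",
    "HA_PER_KM2",
]

DEFAULT_COST_PER_HA: float = 351_661.0
HA_PER_KM2: float = 100.0


@dataclass(frozen=True)
class EffortQuery:
    """One effort/cost question: reef size, rate, targeted fraction, duration."""

    reef_area_km2: float
    rate: float  # supplementation level, fraction of target area per year
    fraction_targeted: float = 0.2
    years: float = 100.0
    cost_per_ha: float = DEFAULT_COST_PER_HA

    def __post_init__(self) -> None:
        if min(self.reef_area_km2, self.rate, self.years, self.cost_per_ha) < 0:
            raise ValueError("effort query fields must be non-negative")
        if not 0 <= self.fraction_targeted <= 1:
            raise ValueError(
                f"fraction_targeted must be in [0, 1], got {self.fraction_targeted}"
            )


def annual_input_area(q: EffortQuery) -> float:
    """Hectares of coral added per year: targeted area times the rate."""
    return q.fraction_targeted * q.reef_area_km2 * HA_PER_KM2 * q.rate


def total_effort(annual_ha: float, years: float) -> float:
    """Cumulative outplanted area (ha) over a sustained program."""
    if annual_ha < 0 or years < 0:
        raise ValueError("inputs must be non-negative")
    return annual_ha * years


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig_figs - 1 - math.floor(math.log10(abs(x))))


def annual_cost(annual_ha: float, cost_per_ha: float = DEFAULT_COST_PER_HA, sig_figs: int | None = None) -> float:
    """Annual program cost (USD/yr), optionally rounded for reporting."""
    if annual_ha < 0 or cost_per_ha < 0:
        raise ValueError("inputs must be non-negative")
    cost = annual_ha * cost_per_ha
    return cost if sig_figs is None else round_sig(cost, sig_figs)


def genetic_variance_from_heritability(phenotypic_variance: float, h2: float) -> float:
    """Additive genetic variance as phenotypic variance times narrow-sense h^2."""
    if phenotypic_variance < 0:
        raise ValueError("phenotypic variance must be >= 0")
    if not 0 <= h2 <= 1:
        raise ValueError(f"narrow-sense heritability must be in [0, 1], got {h2}")
    return phenotypic_variance * h2
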