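"""Synthetic temperature forcing: spatial gradient, warming trend, anomalies.

The only exogenous input of the simulation.  Per-patch baselines span a fixed
spatial gradient (default 3 degC around a 27 degC network mean, coldest
first).  Climate change adds a network-uniform, asymptotically saturating
warming trend (default 5 degC, ~95 % realized within 200 years) on top of the
baselines, and every year carries a network-wide stochastic anomaly drawn
from N(0, sigma^2) (default sigma = 0.3 degC) shared by all patches.

Temperatures are piecewise-constant within each year: the within-year ODE
integration sees a fixed per-patch temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClimateForcing",
    "baseline_gradient",
    "warming_trend",
    "sample_anomalies",
    "temperature_series",
    "DEFAULT_TAU",
]

#: Warming e-folding timescale (years) giving ~95 % of the rise within 200 yr.
DEFAULT_TAU: float = 200.0 / 3.0


def baseline_gradient(n_reefs: int, mean_T: float = 27.0, span: float = 3.0) -> np.ndarray:
    """Evenly spaced per-patch baseline temperatures, coldest to hottest.

    Spans ``[mean_T - span/2, mean_T + span/2]``; the mean equals ``mean_T``
    exactly.
    """
    if n_reefs < 2:
        raise ValueError(f"need at least 2 reef patches, got {n_reefs}")
    if span < 0:
        raise ValueError(f"gradient span must be >= 0, got {span}")
    return np.linspace(mean_T - span / 2.0, mean_T + span / 2.0, n_reefs)


def warming_trend(t, deltaT: float = 5.0, tau: float = DEFAULT_TAU):
    """Saturating-exponential warming offset ``deltaT * (1 - exp(-t/tau))`` (degC).

    Zero at warming onset, asymptoting to ``deltaT``; identical across all
    patches (uniform warming).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("years since warming onset must be >= 0")
    return deltaT * -np.expm1(-t / tau)


def sample_anomalies(n_years: int, sigma: float = 0.3, seed: int = 0) -> np.ndarray:
    """i.i.d. annual N(0, sigma^2) anomalies shared network-wide; seeded."""
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    if sigma < 0:
        raise ValueError(f"anomaly sd must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sigma, size=n_years)


@dataclass(frozen=True)
class ClimateForcing:
    """Full temperature forcing for one replicate.

    One anomaly stream covers burn-in then monitoring, so a replicate's
    forcing is identical across scenarios sharing its seed (common random
    numbers for scenario contrasts).
    """

    n_reefs: int = 20
    mean_T: float = 27.0
    span: float = 3.0
    deltaT: float = 5.0
    tau: float = DEFAULT_TAU
    sigma_anom: float = 0.3
    burn_in_years: int = 1000
    monitor_years: int = 500
    seed: int = 0

    @property
    def T0(self) -> np.ndarray:
        return baseline_gradient(self.n_reefs, self.mean_T, self.span)

    @property
    def anomalies(self) -> np.ndarray:
        """Annual anomalies for burn-in followed by monitoring years."""
        return sample_anomalies(
            self.burn_in_years + self.monitor_years, self.sigma_anom, self.seed
        )

    def series(self, phase: str) -> np.ndarray:
        return temperature_series(self, phase)


def temperature_series(fc: ClimateForcing, phase: str) -> np.ndarray:
    """Per-year, per-patch temperature table for one phase, shape (years, reefs).

    ``burn_in``: baselines plus anomalies (stationary mean).  ``warming``:
    baselines plus the uniform trend evaluated at the start of each year plus
    anomalies.  Row ``t`` is the fixed temperature field during year ``t`` of
    the phase.
    """
    T0 = fc.T0
    anomalies = fc.anomalies
    if phase == "burn_in":
        anom = anomalies[: fc.burn_in_years]
        trend = np.zeros(fc.burn_in_years)
    elif phase == "warming":
        anom = anomalies[fc.burn_in_years :]
        trend = warming_trend(np.arange(fc.monitor_years), fc.deltaT, fc.tau)
    else:
        raise ValueError(f"phase must be 'burn_in' or 'warming', got {phase!r}")
    return T0[None, :] + trend[:, None] + anom[:, None]
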