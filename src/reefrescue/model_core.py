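"""Temperature-dependent vital rates, fitness and trait derivatives.

Coral growth is a Gaussian function of the displacement between local
temperature ``T`` and the subpopulation's thermal optimum ``z``; an
additional bleaching-like mortality cost applies only when ``T > z``.
Fitness combines these rates with space competition against macroalgae and
conspecifics.  The analytic first and second trait-derivatives of fitness
drive, respectively, the directional-selection and genetic-load terms of the
trait and cover dynamics.

All rate functions are vectorized over their temperature/trait/state
arguments via numpy broadcasting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .params import CompetitionMatrix, CoralParams, MacroalgaeParams

__all__ = [
    "coral_growth_rate",
    "coral_mortality_rate",
    "free_space",
    "coral_fitness",
    "macroalgal_fitness",
    "fitness_gradient",
    "fitness_curvature",
    "selection_attenuation",
    "RegimeReport",
    "verify_regime",
]


def _check_finite(T, z) -> None:
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(z))):
        raise ValueError("temperature and thermal optimum must be finite")


def _gauss_norm(p: CoralParams) -> float:
    return p.r_C0 / np.sqrt(2.0 * np.pi * p.w**2)


def coral_growth_rate(T, z, p: CoralParams):
    """Gaussian thermal performance curve for coral growth (1/yr).

    ``r_C0 / sqrt(2 pi w^2) * exp(-(T - z)^2 / d)`` with ``d`` set by the
    exponent convention (default ``2 w^2``).  Maximal at ``T == z`` and
    symmetric in the displacement ``T - z``.
    """
    _check_finite(T, z)
    d = np.asarray(T, dtype=float) - z
    return _gauss_norm(p) * np.exp(-(d**2) / p.exponent_divisor)


def coral_mortality_rate(T, z, p: CoralParams):
    """Excess-temperature coral mortality (1/yr); zero when ``T <= z``.

    ``1 - exp(-(T - z)^2 / d)`` for ``T > z``: the bleaching cost rises
    monotonically with thermal excess and saturates below 1.
    """
    _check_finite(T, z)
    d = np.asarray(T, dtype=float) - z
    hot = d > 0
    return np.where(hot, -np.expm1(-(d**2) / p.exponent_divisor), 0.0)


def free_space(C, M, tol: float = 1e-8):
    """Habitat fraction unoccupied by coral or macroalgae, ``max(0, 1-C-M)``."""
    C = np.asarray(C, dtype=float)
    M = np.asarray(M, dtype=float)
    total = C + M
    if np.any(total > 1.0 + tol):
        raise ValueError(f"cover sum C + M = {np.max(total)} exceeds 1")
    return np.clip(1.0 - total, 0.0, 1.0)


def _competition_term(C, M, a: CompetitionMatrix):
    return 1.0 - a.alpha_CM * np.asarray(M, dtype=float) - a.alpha_CC * np.asarray(
        C, dtype=float
    )


def coral_fitness(T, z, C, M, p: CoralParams, a: CompetitionMatrix):
    """Per-capita coral fitness g_C (1/yr): growth under competition minus mortality."""
    return coral_growth_rate(T, z, p) * _competition_term(C, M, a) - coral_mortality_rate(
        T, z, p
    )


def macroalgal_fitness(C, M, mp: MacroalgaeParams, a: CompetitionMatrix):
    """Per-capita macroalgal fitness g_M (1/yr); independent of temperature."""
    C = np.asarray(C, dtype=float)
    M = np.asarray(M, dtype=float)
    return mp.r_M0 * (1.0 - a.alpha_MC * C - a.alpha_MM * M) - mp.m_M0


def fitness_gradient(T, z, C, M, p: CoralParams, a: CompetitionMatrix):
    """Analytic d(g_C)/dz at the current optimum (1/yr per degC).

    The growth term contributes everywhere; the mortality term only for
    ``T > z`` (the mortality kernel is C1-continuous at ``T == z``, so the
    boundary point is assigned the cool branch).  Positive whenever ``T > z``:
    warming selects for higher thermal optima.
    """
    _check_finite(T, z)
    d = np.asarray(T, dtype=float) - z
    dd = p.exponent_divisor
    e = np.exp(-(d**2) / dd)
    growth = _gauss_norm(p) * e * (2.0 * d / dd) * _competition_term(C, M, a)
    mort = np.where(d > 0, e * (2.0 * d / dd), 0.0)
    return growth + mort


def fitness_curvature(T, z, C, M, p: CoralParams, a: CompetitionMatrix):
    """Analytic d2(g_C)/dz2 clamped to be non-positive (1/yr per degC^2).

    The genetic-load penalty on population growth is ``V/2`` times this
    curvature; the raw second derivative of the mortality branch can turn
    positive far in the hot tail, so the value is clamped at zero from above
    to keep the load a pure cost.
    """
    _check_finite(T, z)
    d = np.asarray(T, dtype=float) - z
    dd = p.exponent_divisor
    e = np.exp(-(d**2) / dd)
    s = 2.0 * d / dd
    growth = _gauss_norm(p) * e * (s**2 - 2.0 / dd) * _competition_term(C, M, a)
    mort = np.where(d > 0, e * (2.0 / dd - s**2), 0.0)
    return np.minimum(growth - mort, 0.0)


def selection_attenuation(C, C_min: float):
    """Directional-selection attenuation q at vanishing cover.

    ``q = max(0, 1 - C_min / max(C_min^2, C))``: zero at or below the
    vanishing-cover threshold, approaching 1 for cover well above it.
    """
    if not C_min > 0:
        raise ValueError("C_min must be > 0")
    C = np.asarray(C, dtype=float)
    return np.maximum(0.0, 1.0 - C_min / np.maximum(C_min**2, C))


def selection_attenuation_squared(C, C_min: float):
    """Alternative reading of the attenuation: ``max(0, 1 - (C_min/max(C_min, C))^2)``."""
    if not C_min > 0:
        raise ValueError("C_min must be > 0")
    C = np.asarray(C, dtype=float)
    return np.maximum(0.0, 1.0 - (C_min / np.maximum(C_min, C)) ** 2)


# ---------------------------------------------------------------------------
# Regime certification of the local two-species subsystem
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegimeReport:
    """Outcome of the nullcline/Jacobian analysis of the (C, M) subsystem."""

    regime: str
    equilibria: tuple  # ((C, M, stable), ...)

    @property
    def stable_equilibria(self) -> tuple:
        return tuple(eq for eq in self.equilibria if eq[2])


def verify_regime(
    a: CompetitionMatrix,
    cp: CoralParams,
    mp: MacroalgaeParams,
    T: float = 27.0,
    tol: float = 1e-9,
) -> RegimeReport:
    """Classify the local coral/macroalgae subsystem at thermal optimum.

    Evaluated at ``T == z`` (so coral mortality vanishes), without dispersal:
    ``dC/dt = g_C C`` and ``dM/dt = g_M M``.  All non-negative equilibria are
    found from the nullcline intersections, their local stability from the
    numerically evaluated Jacobian, and the system is classified as

    - ``"bistable"`` if at least two locally stable equilibria with distinct
      dominance (coral-dominated and macroalgae-dominated) exist,
    - ``"coexistence"`` if a unique stable interior equilibrium exists,
    - ``"indeterminate"`` if some Jacobian is degenerate (an eigenvalue real
      part within ``tol`` of zero),
    - ``"other"`` otherwise.
    """
    z = float(T)

    def rhs(y):
        C, M = y
        gC = coral_fitness(T, z, C, M, cp, a)
        gM = macroalgal_fitness(C, M, mp, a)
        return np.array([gC * C, gM * M])

    peak = float(coral_growth_rate(T, z, cp))  # m_C = 0 at T = z

    equilibria: list[tuple[float, float]] = [(0.0, 0.0)]
    # boundary equilibria: r_C (1 - alpha_CC C) = 0  /  r_M0 (1 - alpha_MM M) = m_M0
    if a.alpha_CC > 0 and peak > 0:
        equilibria.append((1.0 / a.alpha_CC, 0.0))
    if mp.r_M0 > 0 and a.alpha_MM > 0:
        M1 = (1.0 - mp.m_M0 / mp.r_M0) / a.alpha_MM
        if M1 > 0:
            equilibria.append((0.0, M1))
    # interior: alpha_CC C + alpha_CM M = 1 and alpha_MC C + alpha_MM M = 1 - m/r
    if mp.r_M0 > 0:
        A = np.array([[a.alpha_CC, a.alpha_CM], [a.alpha_MC, a.alpha_MM]])
        b = np.array([1.0, 1.0 - mp.m_M0 / mp.r_M0])
        if abs(np.linalg.det(A)) > tol:
            Ci, Mi = np.linalg.solve(A, b)
            if Ci > tol and Mi > tol:
                equilibria.append((float(Ci), float(Mi)))

    # polish and classify
    classified = []
    degenerate = False
    for C0, M0 in equilibria:
        sol = optimize.root(rhs, [C0, M0], tol=1e-13)
        C_eq, M_eq = (sol.x if sol.success else (C0, M0))
        if C_eq < -tol or M_eq < -tol:
            continue
        jac = optimize.approx_fprime(np.array([C_eq, M_eq]), rhs, 1e-7)
        eig = np.linalg.eigvals(jac)
        if np.any(np.abs(eig.real) < tol):
            degenerate = True
            stable = False
        else:
            stable = bool(np.all(eig.real < 0))
        classified.append((float(max(C_eq, 0.0)), float(max(M_eq, 0.0)), stable))

    report_eqs = tuple(classified)
    if degenerate:
        return RegimeReport("indeterminate", report_eqs)

    stable_eqs = [eq for eq in classified if eq[2]]
    coral_dom = [eq for eq in stable_eqs if eq[0] > eq[1]]
    algae_dom = [eq for eq in stable_eqs if eq[1] > eq[0]]
    interior = [eq for eq in stable_eqs if eq[0] > tol and eq[1] > tol]

    if coral_dom and algae_dom:
        return RegimeReport("bistable", report_eqs)
    if len(stable_eqs) == 1 and interior:
        return RegimeReport("coexistence", report_eqs)
    return RegimeReport("other", report_eqs)
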