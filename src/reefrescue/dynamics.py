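"""Coupled cover/trait dynamics across the reef network and their integration.

Per reef patch ``a`` the model integrates three coupled equations:

- coral cover:  ``dC_a/dt = g_C C_a + l_a F_a + (V/2) (d2g_C/dz2) C_a``
  (population dynamics + larval settlement into free space + genetic load),
- thermal optimum:  ``dz_a/dt = (z_i,a - z_a) l_a F_a / max(C_a, C_min)
  + q_a V (dg_C/dz)``  (gene flow + directional selection),
- macroalgal cover:  ``dM_a/dt = g_M M_a``.

Temperatures are piecewise-constant within a year; yearly events (anomaly
switch, nursery trait re-definition, supplementation duration cutoff) are
applied at integer-year boundaries, in that order.  Nursery patches are not
integrated: their cover and trait are externally imposed and enter only
through the dispersal terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint

from .network import ReefNetwork
from .params import CompetitionMatrix, CoralParams, MacroalgaeParams

__all__ = [
    "SystemState",
    "IntegratorSettings",
    "IntegrationError",
    "system_rhs",
    "integrate_years",
    "apply_supplementation_hook",
]


class IntegrationError(RuntimeError):
    """Raised when the within-year ODE solve fails or produces invalid state."""


@dataclass
class SystemState:
    """Dynamical state of all reef patches plus imposed nursery values.

    ``C``, ``M``, ``z`` are per-reef arrays; ``nursery_C`` / ``nursery_z``
    are the externally pinned nursery covers and traits (empty arrays when
    no nurseries are attached).  ``time`` is in years from the start of the
    current phase.
    """

    C: np.ndarray
    M: np.ndarray
    z: np.ndarray
    time: float = 0.0
    nursery_C: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nursery_z: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def copy(self) -> "SystemState":
        return SystemState(
            C=self.C.copy(),
            M=self.M.copy(),
            z=self.z.copy(),
            time=self.time,
            nursery_C=self.nursery_C.copy(),
            nursery_z=self.nursery_z.copy(),
        )

    @property
    def full_cover(self) -> np.ndarray:
        """Cover vector over reefs then nurseries, as consumed by dispersal."""
        return np.concatenate([self.C, self.nursery_C])

    @property
    def full_trait(self) -> np.ndarray:
        return np.concatenate([self.z, self.nursery_z])


@dataclass(frozen=True)
class IntegratorSettings:
    """Within-year ODE solver configuration.

    ``method`` is ``"lsoda"`` (adaptive, handles the stiff gene-flow
    relaxation at vanishing cover) or ``"rk4"`` (fixed step of ``max_step``
    years, reference integrator).  Cover bound violations beyond
    ``clamp_tol`` trigger a retry at tightened tolerances rather than
    renormalization.
    """

    method: str = "lsoda"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = 0.05
    clamp_tol: float = 1e-8
    max_retries: int = 3

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.max_step <= 0 or self.clamp_tol <= 0:
            raise ValueError("integrator tolerances and step must be > 0")
        if self.method not in ("lsoda", "rk4"):
            raise ValueError(f"unknown integrator method {self.method!r}")


def _rhs_arrays(
    C: np.ndarray,
    M: np.ndarray,
    z: np.ndarray,
    T: np.ndarray,
    net: ReefNetwork,
    cp: CoralParams,
    mp: MacroalgaeParams,
    a: CompetitionMatrix,
    nursery_C: np.ndarray,
    nursery_z: np.ndarray,
):
    """Time derivatives (dC, dM, dz) for the reef patches.

    Fused evaluation of the vital-rate kernels (one shared exponential)
    equivalent term-by-term to composing the public ``model_core``
    operations; the equivalence is asserted in the test suite.
    """
    if nursery_C.size:
        full_C = np.concatenate([C, nursery_C])
        full_z = np.concatenate([z, nursery_z])
    else:
        full_C, full_z = C, z

    reef_rows = net.reef_rows
    l = cp.beta * (reef_rows @ full_C)
    num = cp.beta * (reef_rows @ (full_C * full_z))
    has_l = l > 0
    zi = np.where(has_l, num / np.where(has_l, l, 1.0), z)
    F = np.clip(1.0 - C - M, 0.0, 1.0)

    d = T - z
    dd = cp.exponent_divisor
    e = np.exp(-(d * d) / dd)
    amp = cp.r_C0 / np.sqrt(2.0 * np.pi * cp.w**2)
    hot = (d > 0).astype(float)
    comp = 1.0 - a.alpha_CM * M - a.alpha_CC * C
    gC = amp * e * comp - hot * (1.0 - e)
    settle = l * F

    dC = gC * C + settle
    dz = (zi - z) * settle / np.maximum(C, cp.C_min)
    if cp.V > 0:
        s = 2.0 * d / dd
        kernel = e * (amp * comp + hot)
        curv = np.minimum(kernel * (s * s - 2.0 / dd), 0.0)
        grad = kernel * s
        q = np.maximum(0.0, 1.0 - cp.C_min / np.maximum(cp.C_min**2, C))
        dC = dC + 0.5 * cp.V * curv * C
        dz = dz + q * cp.V * grad
    dM = (mp.r_M0 * (1.0 - a.alpha_MC * C - a.alpha_MM * M) - mp.m_M0) * M
    return dC, dM, dz


def system_rhs(
    state: SystemState,
    T: np.ndarray,
    net: ReefNetwork,
    cp: CoralParams,
    mp: MacroalgaeParams,
    a: CompetitionMatrix,
):
    """Per-patch time derivatives at the given temperature field.

    Returns ``(dC, dM, dz)`` for the reef patches; nursery patches are pinned
    (their derivatives are identically zero and are not returned).
    """
    T = np.asarray(T, dtype=float)
    if T.shape != (net.n_reefs,):
        raise ValueError(f"temperature field must have {net.n_reefs} entries")
    dC, dM, dz = _rhs_arrays(
        state.C, state.M, state.z, T, net, cp, mp, a, state.nursery_C, state.nursery_z
    )
    for name, arr in (("dC/dt", dC), ("dM/dt", dM), ("dz/dt", dz)):
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise IntegrationError(f"non-finite {name} at patch {bad}")
    return dC, dM, dz


def _integrate_one_year(
    y0: np.ndarray,
    n: int,
    T: np.ndarray,
    net: ReefNetwork,
    cp: CoralParams,
    mp: MacroalgaeParams,
    a: CompetitionMatrix,
    nursery_C: np.ndarray,
    nursery_z: np.ndarray,
    settings: IntegratorSettings,
) -> np.ndarray:
    def f(y, t):
        dC, dM, dz = _rhs_arrays(
            y[:n], y[n : 2 * n], y[2 * n :], T, net, cp, mp, a, nursery_C, nursery_z
        )
        return np.concatenate([dC, dM, dz])

    if settings.method == "rk4":
        steps = max(1, int(round(1.0 / settings.max_step)))
        h = 1.0 / steps
        y = y0
        for i in range(steps):
            t = i * h
            k1 = f(y, t)
            k2 = f(y + 0.5 * h * k1, t + 0.5 * h)
            k3 = f(y + 0.5 * h * k2, t + 0.5 * h)
            k4 = f(y + h * k3, t + h)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return y

    out = odeint(
        f,
        y0,
        [0.0, 1.0],
        rtol=settings.rtol,
        atol=settings.atol,
        mxstep=100_000,
    )
    return out[1]


def _clamp(y: np.ndarray, n: int, tol: float) -> np.ndarray | None:
    """Clip solver overshoot within tolerance; return None if beyond tolerance."""
    C, M = y[:n], y[n : 2 * n]
    if np.min(C) < -tol or np.min(M) < -tol:
        return None
    total = C + M
    if np.max(total) > 1.0 + tol:
        return None
    C = np.clip(C, 0.0, 1.0)
    M = np.minimum(np.clip(M, 0.0, 1.0), 1.0 - C)
    return np.concatenate([C, M, y[2 * n :]])


def integrate_years(
    state0: SystemState,
    forcing: np.ndarray,
    years: int,
    net: ReefNetwork,
    cp: CoralParams,
    mp: MacroalgaeParams,
    a: CompetitionMatrix,
    settings: IntegratorSettings | None = None,
    hooks=(),
) -> list[SystemState]:
    """Integrate the network over ``years`` one-year blocks of fixed forcing.

    ``forcing`` is a (years, n_reefs) temperature table; row ``t`` applies
    during year ``t``.  At each year boundary the per-year ``hooks`` are
    applied in order (each maps ``(year, state) -> state``; this is where
    nursery traits and supplementation on/off are imposed), then the ODE is
    integrated across the year.  Returns annual snapshots: the initial state
    followed by one state per completed year.
    """
    if settings is None:
        settings = IntegratorSettings()
    forcing = np.asarray(forcing, dtype=float)
    n = state0.C.size
    if years > 0 and (forcing.ndim != 2 or forcing.shape[0] < years or forcing.shape[1] != n):
        raise ValueError(
            f"forcing shape {forcing.shape} does not cover {years} years x {n} reefs"
        )

    snapshots = [state0.copy()]
    state = state0.copy()
    for year in range(years):
        for hook in hooks:
            state = hook(year, state)
        T = forcing[year]
        y = np.concatenate([state.C, state.M, state.z])
        trial = settings
        for attempt in range(settings.max_retries + 1):
            y1 = _integrate_one_year(
                y, n, T, net, cp, mp, a, state.nursery_C, state.nursery_z, trial
            )
            if not np.all(np.isfinite(y1)):
                clamped = None
            else:
                clamped = _clamp(y1, n, settings.clamp_tol)
            if clamped is not None:
                break
            # solver overshoot beyond clamp tolerance: retry more strictly
            trial = replace(
                trial,
                rtol=trial.rtol / 100.0,
                atol=trial.atol / 100.0,
                max_step=trial.max_step / 4.0,
            )
        else:
            raise IntegrationError(
                f"cover bounds violated beyond tolerance in year {year} "
                f"(min C = {np.min(y1[:n]):.3e}, max C+M = "
                f"{np.max(y1[:n] + y1[n:2 * n]):.3e})"
            )
        state = SystemState(
            C=clamped[:n],
            M=clamped[n : 2 * n],
            z=clamped[2 * n :],
            time=state.time + 1.0,
            nursery_C=state.nursery_C.copy(),
            nursery_z=state.nursery_z.copy(),
        )
        snapshots.append(state.copy())
    return snapshots


def apply_supplementation_hook(
    state: SystemState,
    plan,
    year: int,
    net: ReefNetwork,
    beta: float,
) -> SystemState:
    """Impose nursery covers and traits for one year of the intervention.

    While ``year < plan.duration`` each nursery's cover is pinned at
    ``C_s = rate / beta`` (so the maximum potential supplementation rate is
    ``beta * C_s = rate``) and its trait at the target reef's current mean
    thermal optimum plus the enhancement ``delta_Z``; afterwards nursery
    cover is zero and the nursery exports no larvae.
    """
    if net.n_nurseries == 0:
        return state
    state = state.copy()
    targets = np.asarray(net.nursery_targets, dtype=int)
    if year < plan.duration and plan.rate > 0:
        if beta <= 0:
            raise ValueError("supplementation requires beta > 0")
        state.nursery_C = np.full(net.n_nurseries, plan.rate / beta)
        state.nursery_z = state.z[targets] + plan.delta_Z
    else:
        state.nursery_C = np.zeros(net.n_nurseries)
        state.nursery_z = state.z[targets]
    return state
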