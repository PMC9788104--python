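"""Restoration scenario axes: spatial strategy, rate, enhancement, duration.

An :class:`InterventionPlan` fixes the four intervention axes of a scenario:
which reefs receive nursery outplanting (``hot`` / ``cold`` / ``random`` /
``none``), the maximum annual supplementation rate ``beta * C_s`` (fraction
of target reef area per year), the thermal-optimum enhancement of outplanted
corals relative to the target reef's current mean trait (degC), and the
number of years supplementation is sustained after warming onset.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["InterventionPlan", "select_targets", "build_plan_grid", "ScenarioSpec"]

#: Default scenario-axis values spanning the full experimental design.
DEFAULT_RATES = (0.0, 1e-7, 1e-6, 1e-5, 1e-4)
DEFAULT_DELTA_Z = (0.0, 1.0, 2.0, 3.0)
DEFAULT_STRATEGIES = ("hot", "cold", "random")
DEFAULT_V_LEVELS = (0.0, 0.05, 0.1)
DEFAULT_DURATIONS = (500,)


@dataclass(frozen=True)
class InterventionPlan:
    """Value-object describing one restoration scenario's intervention.

    ``rate`` is the maximum potential supplementation rate ``beta * C_s``
    (realized input is further scaled by free space at the target).
    ``redraw_targets`` controls whether the random strategy redraws its
    target set per replicate (portfolio interpretation, default) or fixes one
    set per scenario via ``strategy_seed``.
    """

    strategy: str = "none"
    n_targets: int = 4
    rate: float = 0.0
    delta_Z: float = 0.0
    duration: int = 500
    strategy_seed: int = 0
    redraw_targets: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in ("hot", "cold", "random", "none"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.rate < 0:
            raise ValueError(f"supplementation rate must be >= 0, got {self.rate}")
        if self.delta_Z < 0:
            raise ValueError(f"trait enhancement must be >= 0, got {self.delta_Z}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")

    @property
    def active(self) -> bool:
        """Whether the plan adds any larvae at all."""
        return self.strategy != "none" and self.rate > 0 and self.n_targets > 0

    def targets_for(
        self, baselines: np.ndarray, replicate: int = 0, base_seed: int = 0
    ) -> tuple[int, ...]:
        """Resolve the target set for one replicate.

        The random strategy is seeded from ``(base_seed, strategy_seed,
        replicate)`` so the draw is reproducible and, by default, redrawn per
        replicate; with ``redraw_targets=False`` one fixed set is used for
        every replicate of the scenario.
        """
        if not self.active:
            return ()
        seed = (base_seed, self.strategy_seed, replicate) if self.redraw_targets else (
            base_seed,
            self.strategy_seed,
        )
        return select_targets(self.strategy, baselines, self.n_targets, seed)

    def with_(self, **kwargs) -> "InterventionPlan":
        return replace(self, **kwargs)


def select_targets(strategy: str, baselines, n_targets: int, seed=0) -> tuple[int, ...]:
    """Pick reef indices to supplement by thermal regime.

    ``hot``: the ``n_targets`` highest-baseline patches; ``cold``: the lowest;
    ``random``: a uniform sample without replacement (reproducible under
    ``seed``); ``none``: empty.
    """
    baselines = np.asarray(baselines, dtype=float)
    n = baselines.size
    if n_targets > n:
        raise ValueError(f"cannot target {n_targets} of {n} reefs")
    if strategy == "none":
        return ()
    order = np.argsort(baselines, kind="stable")
    if strategy == "cold":
        return tuple(int(i) for i in sorted(order[:n_targets]))
    if strategy == "hot":
        return tuple(int(i) for i in sorted(order[n - n_targets :]))
    if strategy == "random":
        rng = np.random.default_rng(seed)
        return tuple(int(i) for i in sorted(rng.choice(n, size=n_targets, replace=False)))
    raise ValueError(f"unknown strategy {strategy!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """One point of the scenario grid: an intervention plan plus biology axes."""

    plan: InterventionPlan
    V: float
    beta: float = 0.01
    competition: str = "bistable"

    @property
    def scenario_id(self) -> str:
        """Stable, human-readable identifier (hashable for caching/resume)."""
        p = self.plan
        key = (
            f"{p.strategy}_n{p.n_targets}_rate{p.rate:g}_dZ{p.delta_Z:g}"
            f"_dur{p.duration}_V{self.V:g}_beta{self.beta:g}_{self.competition}"
        )
        digest = hashlib.sha1(
            (key + f"_seed{p.strategy_seed}_redraw{p.redraw_targets}").encode()
        ).hexdigest()[:8]
        return f"{key}_{digest}"


def build_plan_grid(
    strategies=DEFAULT_STRATEGIES,
    rates=DEFAULT_RATES,
    delta_Zs=DEFAULT_DELTA_Z,
    durations=DEFAULT_DURATIONS,
    V_levels=DEFAULT_V_LEVELS,
    beta: float = 0.01,
    competition: str = "bistable",
    n_targets: int = 4,
) -> list[ScenarioSpec]:
    """Full Cartesian product of the scenario axes.

    Every combination is kept (rate-0 cells of each strategy all behave as
    the no-intervention baseline, so the baseline is present for every V);
    with the default axes this yields 3 x 5 x 4 x 3 = 180 scenarios at a
    single duration.
    """
    specs: list[ScenarioSpec] = []
    for strat, rate, dZ, dur, V in itertools.product(
        strategies, rates, delta_Zs, durations, V_levels
    ):
        plan = InterventionPlan(
            strategy=strat, n_targets=n_targets, rate=rate, delta_Z=dZ, duration=dur
        )
        specs.append(ScenarioSpec(plan=plan, V=V, beta=beta, competition=competition))
    return specs
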