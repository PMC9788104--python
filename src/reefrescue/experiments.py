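"""Replicate protocol, summary metrics and scenario-grid execution.

A replicate initializes every reef at 25 % coral cover with thermal optima
matching local baseline temperature, equilibrates for a 1000-year burn-in
(stationary mean temperature, stochastic anomalies on), then monitors 500
years of warming with the scenario's intervention plan active.  Replicate
``r`` of every scenario shares its anomaly stream (common random numbers),
so scenario contrasts are not confounded by forcing noise.

Summary metrics follow the study design: per-year medians with central 50 %
and 80 % quantile bands of network-mean coral cover across replicates, the
median final (year-500) cover, and the median across replicates of each
replicate's minimum cover over the monitoring window.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClimateForcing, baseline_gradient
from .dynamics import (
    IntegrationError,
    IntegratorSettings,
    SystemState,
    apply_supplementation_hook,
    integrate_years,
)
from .interventions import ScenarioSpec
from .network import attach_nurseries, build_ring_lattice
from .params import (
    CompetitionMatrix,
    CoralParams,
    MacroalgaeParams,
    competition_preset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ReplicateResult",
    "ScenarioResult",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "network_mean_cover",
    "summarize_scenario",
]

#: Network-mean cover below which a run is reported as an extinction.
EXTINCT_THRESHOLD = 1e-4


@dataclass(frozen=True)
class RunConfig:
    """Structural and forcing configuration shared by all scenarios of a study.

    ``coral`` is a template whose ``V`` and ``beta`` are overridden by each
    scenario's axes; ``competition`` overrides the scenario's named preset
    when set (otherwise the preset is looked up by name).
    """

    n_reefs: int = 20
    k_neighbors: int = 4
    edge_weight: float = 0.2
    ring_layout: str = "folded"
    mean_T: float = 27.0
    span: float = 3.0
    deltaT: float = 5.0
    tau: float = 200.0 / 3.0
    sigma_anom: float = 0.3
    burn_in_years: int = 1000
    monitor_years: int = 500
    C0: float = 0.25
    M0: float = 0.10
    coral: CoralParams = field(default_factory=CoralParams)
    macroalgae: MacroalgaeParams = field(default_factory=MacroalgaeParams)
    competition: "CompetitionMatrix | None" = None
    settings: IntegratorSettings = field(default_factory=IntegratorSettings)


@dataclass
class ReplicateResult:
    """Annual outputs of one stochastic replicate."""

    replicate: int
    mean_cover: np.ndarray  # network-mean coral cover, years 0..monitor_years
    C: np.ndarray  # per-patch coral cover, shape (years + 1, n_reefs)
    M: np.ndarray
    z: np.ndarray
    burn_in_state: SystemState
    burn_in_ok: bool
    targets: tuple[int, ...]

    @property
    def final_cover(self) -> float:
        return float(self.mean_cover[-1])

    @property
    def min_cover(self) -> float:
        return float(self.mean_cover.min())

    @property
    def extinct(self) -> bool:
        """Network-level extinction: final mean cover below the reporting
        threshold (covers are never floored during integration)."""
        return self.final_cover < EXTINCT_THRESHOLD


@dataclass
class ScenarioResult:
    """Replicate trajectories plus summary metrics for one scenario."""

    scenario_id: str
    spec: ScenarioSpec
    replicates: list[ReplicateResult]
    failed: list[int]
    metrics: dict

    @property
    def mean_cover_matrix(self) -> np.ndarray:
        return np.vstack([r.mean_cover for r in self.replicates])


def network_mean_cover(state: SystemState) -> float:
    """Unweighted mean coral cover over reef patches (nurseries excluded)."""
    if state.C.size == 0:
        raise ValueError("snapshot has no reef patches")
    return float(np.mean(state.C))


def _burn_in_ok(mean_series: np.ndarray, threshold: float = 1e-3) -> bool:
    """Accept burn-in when the network mean cover trend is below ``threshold``
    per decade.  The trend is measured between the means of the last two
    50-year windows (rescaled per decade) so that annual anomaly noise is
    averaged out."""
    if mean_series.size < 100:
        return True
    last = float(np.mean(mean_series[-50:]))
    prev = float(np.mean(mean_series[-100:-50]))
    return abs(last - prev) / 5.0 < threshold


def run_replicate(
    spec: ScenarioSpec,
    replicate: int,
    base_seed: int = 0,
    config: RunConfig | None = None,
) -> ReplicateResult:
    """Run one stochastic replicate of one scenario.

    Corals start at 25 % cover with optima equal to local baseline
    temperature; macroalgae start at the configured cover.  Burn-in runs
    without intervention; nurseries (if any) activate at warming onset and
    switch off after the plan's duration.
    """
    if config is None:
        config = RunConfig()
    cp = config.coral.with_(V=spec.V, beta=spec.beta)
    mp = config.macroalgae
    alpha = (
        config.competition
        if config.competition is not None
        else competition_preset(spec.competition)
    )

    baselines = baseline_gradient(config.n_reefs, config.mean_T, config.span)
    plan = spec.plan
    targets = plan.targets_for(baselines, replicate, base_seed=base_seed)

    net = build_ring_lattice(
        config.n_reefs, config.k_neighbors, config.edge_weight, config.ring_layout
    )
    if targets:
        net = attach_nurseries(net, targets)

    forcing = ClimateForcing(
        n_reefs=config.n_reefs,
        mean_T=config.mean_T,
        span=config.span,
        deltaT=config.deltaT,
        tau=config.tau,
        sigma_anom=config.sigma_anom,
        burn_in_years=config.burn_in_years,
        monitor_years=config.monitor_years,
        seed=(base_seed, replicate),
    )

    n_nurs = net.n_nurseries
    state = SystemState(
        C=np.full(config.n_reefs, config.C0),
        M=np.full(config.n_reefs, config.M0),
        z=baselines.copy(),
        nursery_C=np.zeros(n_nurs),
        nursery_z=baselines[list(targets)] if targets else np.zeros(0),
    )

    burn = integrate_years(
        state,
        forcing.series("burn_in"),
        config.burn_in_years,
        net,
        cp,
        mp,
        alpha,
        settings=config.settings,
    )
    burn_means = np.array([network_mean_cover(s) for s in burn])
    burn_state = burn[-1]
    burn_state.time = 0.0

    hooks = []
    if n_nurs:
        hooks.append(
            lambda year, st: apply_supplementation_hook(st, plan, year, net, cp.beta)
        )
    monitor = integrate_years(
        burn_state,
        forcing.series("warming"),
        config.monitor_years,
        net,
        cp,
        mp,
        alpha,
        settings=config.settings,
        hooks=hooks,
    )

    return ReplicateResult(
        replicate=replicate,
        mean_cover=np.array([network_mean_cover(s) for s in monitor]),
        C=np.vstack([s.C for s in monitor]),
        M=np.vstack([s.M for s in monitor]),
        z=np.vstack([s.z for s in monitor]),
        burn_in_state=burn_state,
        burn_in_ok=_burn_in_ok(burn_means),
        targets=targets,
    )


def summarize_scenario(mean_cover_matrix: np.ndarray) -> dict:
    """Summary metrics across replicates of network-mean cover series.

    Quantiles use linear interpolation between order statistics; the "80 %
    band" is the central 10th-90th percentile interval and the "50 % band"
    the 25th-75th.  The minimum is taken per replicate over the monitoring
    window, then the median across replicates.
    """
    m = np.atleast_2d(np.asarray(mean_cover_matrix, dtype=float))
    if m.shape[0] < 1:
        raise ValueError("need at least one replicate series")
    finals = m[:, -1]
    minima = m.min(axis=1)
    return {
        "n_replicates": int(m.shape[0]),
        "median_final_cover": float(np.median(finals)),
        "final_cover_q10": float(np.quantile(finals, 0.10)),
        "final_cover_q90": float(np.quantile(finals, 0.90)),
        "median_min_cover": float(np.median(minima)),
        "min_cover_q10": float(np.quantile(minima, 0.10)),
        "min_cover_q90": float(np.quantile(minima, 0.90)),
        "median_series": np.median(m, axis=0),
        "series_q25": np.quantile(m, 0.25, axis=0),
        "series_q75": np.quantile(m, 0.75, axis=0),
        "series_q10": np.quantile(m, 0.10, axis=0),
        "series_q90": np.quantile(m, 0.90, axis=0),
    }


def run_scenario(
    spec: ScenarioSpec,
    n_replicates: int = 50,
    base_seed: int = 0,
    config: RunConfig | None = None,
) -> ScenarioResult:
    """Run all replicates of one scenario and summarize them.

    Replicates whose integration fails are logged and excluded from the
    metrics (an error is raised only if every replicate fails).
    """
    replicates: list[ReplicateResult] = []
    failed: list[int] = []
    for r in range(n_replicates):
        try:
            rep = run_replicate(spec, r, base_seed=base_seed, config=config)
        except IntegrationError as err:
            logger.warning("replicate %d of %s failed: %s", r, spec.scenario_id, err)
            failed.append(r)
            continue
        if not rep.burn_in_ok:
            logger.warning(
                "replicate %d of %s: burn-in drift above threshold", r, spec.scenario_id
            )
        replicates.append(rep)
    if not replicates:
        raise IntegrationError(f"all replicates of scenario {spec.scenario_id} failed")
    metrics = summarize_scenario(np.vstack([r.mean_cover for r in replicates]))
    return ScenarioResult(
        scenario_id=spec.scenario_id,
        spec=spec,
        replicates=replicates,
        failed=failed,
        metrics=metrics,
    )


def _scenario_frame(result: ScenarioResult) -> pd.DataFrame:
    rows = []
    for rep in result.replicates:
        for year, cover in enumerate(rep.mean_cover):
            rows.append((rep.replicate, year, cover))
    return pd.DataFrame(rows, columns=["replicate", "year", "mean_cover"])


def run_grid(
    specs,
    n_replicates: int = 50,
    base_seed: int = 0,
    out_dir: str | Path | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Run a list of scenarios, optionally persisting and resuming.

    With ``out_dir`` set, each scenario's replicate series goes to
    ``trajectories/<scenario_id>.csv`` and a one-row-per-scenario summary
    table to ``grid_summary.csv``; scenarios whose trajectory file already
    exists are skipped (resume) and their stored metrics reused.
    Returns the summary table.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    traj_dir = None
    if out_path is not None:
        traj_dir = out_path / "trajectories"
        traj_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for spec in specs:
        p = spec.plan
        axes = {
            "scenario_id": spec.scenario_id,
            "strategy": p.strategy,
            "rate": p.rate,
            "delta_Z": p.delta_Z,
            "duration": p.duration,
            "V": spec.V,
            "beta": spec.beta,
            "competition": spec.competition,
        }
        traj_file = traj_dir / f"{spec.scenario_id}.csv" if traj_dir else None
        if traj_file is not None and traj_file.exists():
            frame = pd.read_csv(traj_file)
            mat = (
                frame.pivot(index="replicate", columns="year", values="mean_cover")
                .sort_index()
                .to_numpy()
            )
            metrics = summarize_scenario(mat)
            n_failed = 0
        else:
            result = run_scenario(
                spec, n_replicates=n_replicates, base_seed=base_seed, config=config
            )
            metrics = result.metrics
            n_failed = len(result.failed)
            if traj_file is not None:
                _scenario_frame(result).to_csv(traj_file, index=False)
        rows.append(
            {
                **axes,
                "n_replicates": metrics["n_replicates"],
                "n_failed": n_failed,
                "median_final_cover": metrics["median_final_cover"],
                "final_cover_q10": metrics["final_cover_q10"],
                "final_cover_q90": metrics["final_cover_q90"],
                "median_min_cover": metrics["median_min_cover"],
                "min_cover_q10": metrics["min_cover_q10"],
                "min_cover_q90": metrics["min_cover_q90"],
            }
        )
        logger.info(
            "scenario %s: median final %.3f, median min %.4f",
            spec.scenario_id,
            metrics["median_final_cover"],
            metrics["median_min_cover"],
        )
    summary = pd.DataFrame(rows)
    if out_path is not None:
        summary.to_csv(out_path / "grid_summary.csv", index=False)
        manifest = {
            "n_replicates": n_replicates,
            "base_seed": base_seed,
            "n_scenarios": len(rows),
        }
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
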