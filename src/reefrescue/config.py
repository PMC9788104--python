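"""YAML run-configuration parsing.

A run configuration is one YAML document with optional blocks mirroring the
model structure::

    coral:        {r_C0, w, C_min, exponent_convention}
    macroalgae:   {r_M0, m_M0}
    competition:  "bistable" | "coexistence" | {alpha_CC, alpha_CM, alpha_MC, alpha_MM}
    network:      {n_reefs, k_neighbors, edge_weight}
    climate:      {mean_T, span, deltaT, tau, sigma_anom, burn_in_years, monitor_years}
    initial:      {C0, M0}
    integrator:   {method, rtol, atol, max_step, clamp_tol}
    scenario:     {V, beta, strategy, n_targets, rate, delta_Z, duration}

Unspecified keys fall back to the calibrated package defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .dynamics import IntegratorSettings
from .experiments import RunConfig
from .interventions import InterventionPlan, ScenarioSpec
from .params import CompetitionMatrix, CoralParams, MacroalgaeParams

__all__ = ["load_config", "parse_config"]


def _take(block: dict, mapping: dict) -> dict:
    unknown = set(block) - set(mapping)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return {mapping[k]: v for k, v in block.items()}


def parse_config(doc: dict) -> tuple[RunConfig, ScenarioSpec]:
    """Build (RunConfig, ScenarioSpec) from a parsed YAML document."""
    doc = dict(doc or {})

    coral = CoralParams(**dict(doc.get("coral", {})))
    macro = MacroalgaeParams(**dict(doc.get("macroalgae", {})))

    comp_block = doc.get("competition", "bistable")
    if isinstance(comp_block, str):
        competition = None  # resolved by name through the scenario
        comp_name = comp_block
    else:
        competition = CompetitionMatrix(**dict(comp_block))
        comp_name = "custom"

    scenario_block = dict(doc.get("scenario", {}))
    V = scenario_block.pop("V", 0.05)
    beta = scenario_block.pop("beta", 0.01)
    plan = InterventionPlan(**scenario_block)

    run_kwargs = {}
    run_kwargs.update(
        _take(
            dict(doc.get("network", {})),
            {"n_reefs": "n_reefs", "k_neighbors": "k_neighbors", "edge_weight": "edge_weight"},
        )
    )
    run_kwargs.update(
        _take(
            dict(doc.get("climate", {})),
            {
                "mean_T": "mean_T",
                "span": "span",
                "deltaT": "deltaT",
                "tau": "tau",
                "sigma_anom": "sigma_anom",
                "burn_in_years": "burn_in_years",
                "monitor_years": "monitor_years",
            },
        )
    )
    run_kwargs.update(_take(dict(doc.get("initial", {})), {"C0": "C0", "M0": "M0"}))

    settings = IntegratorSettings(**dict(doc.get("integrator", {})))
    config = RunConfig(
        coral=coral,
        macroalgae=macro,
        competition=competition,
        settings=settings,
        **run_kwargs,
    )
    spec = ScenarioSpec(plan=plan, V=V, beta=beta, competition=comp_name)
    return config, spec


def load_config(path: str | Path) -> tuple[RunConfig, ScenarioSpec]:
    """Read a YAML run configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)
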