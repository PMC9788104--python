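"""Parameter containers and named presets for the reef metacommunity model.

The model tracks, on every reef patch, fractional coral cover ``C``,
fractional macroalgal cover ``M`` and the coral subpopulation's mean thermal
optimum ``z`` (degC).  Coral demographic rates are temperature dependent and
peak at ``T == z``; macroalgal rates are constants.  Spatial competition is
encoded in a 2x2 interaction matrix whose parameterization places the local
coral/macroalgae subsystem either in a bistable regime (coral- and
macroalgae-dominated alternative stable states) or in a stable-coexistence
regime.

Numeric defaults for the demographic rates and the two competition presets
are calibrated in-repo (see ``docs/methods.md``): the bistable preset is
certified bistable by :func:`reefrescue.model_core.verify_regime`, settles
well above the 25 % starting cover during burn-in, and yields the
evolutionary-rescue dichotomy between zero and moderate additive genetic
variance under the default warming scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CoralParams",
    "MacroalgaeParams",
    "CompetitionMatrix",
    "COMPETITION_PRESETS",
    "competition_preset",
]


@dataclass(frozen=True)
class CoralParams:
    """Coral demographic and quantitative-genetic parameters.

    Parameters
    ----------
    r_C0
        Growth scaling factor (dimensionless scale of the Gaussian thermal
        performance curve).
    w
        Thermal tolerance width (degC).  Controls both the growth kernel and
        the excess-temperature mortality curve.
    V
        Additive genetic variance of the thermal optimum (degC^2).  Fuels the
        selection response and imposes the genetic-load penalty.
    beta
        Effective fecundity rate (1/yr): larval production per unit cover
        entering the dispersal term.
    C_min
        Vanishing-cover threshold (proportion) below which directional
        selection is switched off and which guards the gene-flow denominator.
    exponent_convention
        ``"half"`` uses the standard Gaussian exponent ``-(T-z)^2 / (2 w^2)``;
        ``"plain"`` uses ``-(T-z)^2 / w^2``.  Both share the normalizer
        ``sqrt(2 pi w^2)``.
    """

    r_C0: float = 0.95
    w: float = 1.25
    V: float = 0.1
    beta: float = 0.01
    C_min: float = 1e-6
    exponent_convention: str = "half"

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError(f"thermal tolerance width w must be > 0, got {self.w}")
        if self.V < 0:
            raise ValueError(f"additive genetic variance V must be >= 0, got {self.V}")
        if self.beta < 0:
            raise ValueError(f"effective fecundity beta must be >= 0, got {self.beta}")
        if not 0 < self.C_min < 1e-2:
            raise ValueError(f"C_min must satisfy 0 < C_min << 1, got {self.C_min}")
        if self.exponent_convention not in ("half", "plain"):
            raise ValueError(
                "exponent_convention must be 'half' or 'plain', got "
                f"{self.exponent_convention!r}"
            )

    @property
    def exponent_divisor(self) -> float:
        """Denominator of the squared thermal displacement in both kernels."""
        return 2.0 * self.w**2 if self.exponent_convention == "half" else self.w**2

    def with_(self, **kwargs) -> "CoralParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MacroalgaeParams:
    """Constant (temperature-independent) macroalgal rates.

    Macroalgae neither evolve nor disperse: they act purely as a local
    spatial competitor whose growth ``r_M0`` and mortality ``m_M0`` are
    constants.
    """

    r_M0: float = 0.09
    m_M0: float = 0.027

    def __post_init__(self) -> None:
        if self.r_M0 < 0:
            raise ValueError(f"r_M0 must be >= 0, got {self.r_M0}")
        if self.m_M0 < 0:
            raise ValueError(f"m_M0 must be >= 0, got {self.m_M0}")

    def with_(self, **kwargs) -> "MacroalgaeParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CompetitionMatrix:
    """Pairwise competition coefficients between coral (C) and macroalgae (M).

    ``alpha_CM`` is the effect of macroalgae on coral, ``alpha_MC`` the effect
    of coral on macroalgae; the diagonal terms are self-limitation.  ``regime``
    is a label for the intended dynamical regime of the local two-species
    subsystem; it must be certified with
    :func:`reefrescue.model_core.verify_regime` before a matrix is used in
    scenario experiments.
    """

    alpha_CC: float
    alpha_CM: float
    alpha_MC: float
    alpha_MM: float
    regime: str = "unverified"

    def __post_init__(self) -> None:
        for name in ("alpha_CC", "alpha_CM", "alpha_MC", "alpha_MM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def with_(self, **kwargs) -> "CompetitionMatrix":
        return replace(self, **kwargs)


# Calibrated in-repo (not literature-sourced): the bistable matrix has a
# stable coral-dominated state at C = 1/alpha_CC and a stable
# macroalgae-dominated state at M = (1 - m_M0/r_M0)/alpha_MM that excludes
# coral (alpha_CM * M > 1); the coexistence matrix satisfies
# alpha_CM * alpha_MC < alpha_CC * alpha_MM with an interior equilibrium whose
# covers sum to < 1.  Certified by verify_regime under the default rate
# parameters.
COMPETITION_PRESETS: dict[str, CompetitionMatrix] = {
    "bistable": CompetitionMatrix(
        alpha_CC=1.09, alpha_CM=1.3, alpha_MC=0.865, alpha_MM=0.8, regime="bistable"
    ),
    "coexistence": CompetitionMatrix(
        alpha_CC=1.2, alpha_CM=0.6, alpha_MC=0.5, alpha_MM=2.0, regime="coexistence"
    ),
}


def competition_preset(name: str) -> CompetitionMatrix:
    """Return a named competition preset (``"bistable"`` or ``"coexistence"``)."""
    try:
        return COMPETITION_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown competition preset {name!r}; "
            f"available: {sorted(COMPETITION_PRESETS)}"
        ) from None
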