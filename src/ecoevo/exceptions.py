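"""Exception hierarchy for the perturbation framework."""


class EcoEvoError(Exception):
    """Base class for all package errors."""


class DegeneratePopulationError(EcoEvoError):
    """Raised when frequencies are requested for an all-zero population."""


class NoEquilibriumError(EcoEvoError):
    """The density equation g(S) f0(u) = h(S) d0(u) has no root in the bracket.

    Also raised by model-specific closed forms when the equilibrium density
    would be non-positive (e.g. death rate exceeding the maximal birth rate).
    """


class UnstableEquilibriumError(EcoEvoError):
    """An unstable ecological equilibrium was passed where a stable one is required."""


class UnmatchedExpansionError(EcoEvoError):
    """Inner long-time limit and outer initial value disagree beyond tolerance."""


class IntegrationError(EcoEvoError):
    """The ODE solver failed or produced non-finite values."""


class GridMismatchError(EcoEvoError):
    """Two trajectories were compared on different time grids or time scales."""
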