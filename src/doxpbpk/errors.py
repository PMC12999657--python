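"""Exception hierarchy shared across the package."""


class DoxPBPKError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DoxPBPKError):
    """Invalid or incomplete run configuration / input tables."""


class BuildError(DoxPBPKError):
    """Structurally invalid model assembly (pathway misconfiguration etc.)."""


class SimulationError(DoxPBPKError):
    """ODE solver failure or a physically inadmissible state.

    Carries ``last_state`` / ``last_time_min`` when the integrator made
    partial progress, so the failing trajectory can be inspected.
    """

    def __init__(self, message, last_time_min=None, last_state=None):
        super().__init__(message)
        self.last_time_min = last_time_min
        self.last_state = last_state


class NCAError(DoxPBPKError):
    """Profile unsuitable for non-compartmental analysis."""


class EvaluationError(DoxPBPKError):
    """Invalid predicted/observed comparison input."""


class ActivityScoreGapWarning(UserWarning):
    """CYP2D6 activity score falls in the unassigned (2.25, 2.5] interval."""


class SmallPopulationWarning(UserWarning):
    """Population too small for stable empirical percentiles."""
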