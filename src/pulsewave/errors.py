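"""Exception hierarchy for the pulse-wave pipeline."""


class PulsewaveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PulsewaveError):
    """Malformed network description, missing terminal, duplicate id, bad preset."""


class TopologyError(ConfigurationError):
    """Network graph is not a connected rooted tree."""


class NumericalStateError(PulsewaveError):
    """Solver reached an invalid state (A <= 0, CFL violation, Newton failure)."""


class EstimationError(PulsewaveError):
    """A wave-analysis estimator received degenerate input."""


class UndefinedIndexError(PulsewaveError):
    """A reflection or arrival-time index is undefined for the given signals."""
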