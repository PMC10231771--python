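"""Exception hierarchy shared across the package."""


class GraphMRError(Exception):
    """Base class for all graphmr errors."""


class FormatError(GraphMRError):
    """A file does not conform to the expected layout."""


class DataError(GraphMRError):
    """Inputs are syntactically fine but unusable (e.g. empty intersection)."""


class ParameterError(GraphMRError, ValueError):
    """An argument is outside its documented range."""


class InsufficientDataError(DataError):
    """Too few observations to carry out an estimation step."""


class InsufficientInstrumentsError(DataError):
    """Fewer instruments survived screening than the method requires."""


class DegenerateModelError(GraphMRError):
    """The likelihood or information matrix is degenerate at the requested point."""


class InferenceUnreliableError(GraphMRError):
    """Too many perturbation fits failed for the resampling summary to be trusted."""


class SimulationConfigError(GraphMRError, ValueError):
    """A generative configuration is internally inconsistent."""


class ConvergenceWarning(UserWarning):
    """An iterative solver terminated without meeting its tolerance."""
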