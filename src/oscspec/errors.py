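"""Exception hierarchy shared across the package.

Every error class maps to a distinct failure mode of the analysis
pipeline so that callers (and the CLI exit codes) can branch on them.
"""


class OscspecError(Exception):
    """Base class for all package-specific errors."""


class SamplingGridError(OscspecError):
    """Time grid is not strictly increasing and uniform, or too short."""


class ConfigError(OscspecError):
    """Invalid configuration: parameter values, regions, windows, files."""


class DegenerateInputError(OscspecError):
    """Input is formally valid but degenerate for the requested operation
    (e.g. zero amplitude where a ratio is required)."""


class ModelInconsistencyError(OscspecError):
    """The data contradict a structural prediction of the model; this is
    the invalidation signal, not a numerical failure."""


class IntegrationError(OscspecError):
    """Numerical integration produced non-finite state or exceeded its
    step budget."""


class FlatSignalError(OscspecError):
    """No detectable oscillation in a trajectory."""


class NotConvergedError(OscspecError):
    """Trajectory has not settled onto a steady cycle (drift or damping)."""
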