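"""Exception hierarchy shared across the package."""


class StopvarError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StopvarError):
    """A task/cohort/pipeline configuration violates its invariants."""


class ParameterError(StopvarError):
    """A model parameter is outside its support."""


class DataError(StopvarError):
    """Trial or imaging data are inconsistent with what an operation needs."""
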