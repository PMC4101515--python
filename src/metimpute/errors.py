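"""Exception hierarchy used throughout the package."""


class MetimputeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetimputeError, ValueError):
    """Invalid configuration or out-of-range parameter."""


class DataError(MetimputeError, ValueError):
    """Input data violates a documented precondition."""


class OrderingError(DataError):
    """A stage was invoked out of the required pipeline order
    (e.g. autoscaling before imputation)."""
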