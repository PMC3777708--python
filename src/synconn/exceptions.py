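"""Package exception types."""


class SynconnError(Exception):
    """Base class for all package errors."""


class ConfigError(SynconnError, ValueError):
    """Invalid configuration (bad parameter combination, non-PSD covariance, ...)."""


class DataError(SynconnError, ValueError):
    """Invalid or degenerate input data (non-square matrix, zero-variance node, ...)."""


class DisconnectedGraphError(SynconnError, ValueError):
    """A graph metric requiring connectedness was asked of a disconnected graph."""

    def __init__(self, message: str, failing_levels=None):
        super().__init__(message)
        self.failing_levels = list(failing_levels) if failing_levels is not None else []
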