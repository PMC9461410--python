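"""Exception hierarchy shared across the pipeline stages."""


class VaxwatchError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(VaxwatchError):
    """Invalid configuration value (bad probability vector, negative scale, ...)."""


class VocabularyError(VaxwatchError):
    """A symptom token is outside the controlled vocabulary."""


class SchemaError(VaxwatchError):
    """Input data violates the expected CSV schema or type contract."""


class ExclusionSignal(VaxwatchError):
    """A participant cannot be processed and must be excluded upstream."""


class ConvergenceError(VaxwatchError):
    """Iterative estimation failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
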