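"""Exception hierarchy shared across the package."""


class CognatreeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CognatreeError):
    """Invalid or inconsistent analysis configuration."""


class DataError(CognatreeError):
    """Malformed or degenerate input data."""


class SelectionError(CognatreeError):
    """A language/feature selection produced an empty or invalid set."""


class CladeLookupError(CognatreeError):
    """A clade name or code could not be resolved in the classification."""


class ModelError(CognatreeError):
    """Invalid substitution-model, clock or prior parameterisation."""
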