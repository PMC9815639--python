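"""Exception types shared across the pipeline."""


class PenwatchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PenwatchError):
    """Invalid simulation, window, or pipeline configuration."""


class IntegrityError(PenwatchError):
    """Input records violate referential or range constraints."""


class StructuralError(PenwatchError):
    """Structurally impossible request (e.g. TB pen without a TB date)."""


class ImputationError(PenwatchError):
    """A herd x variable stratum has no observed values to impute from."""
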