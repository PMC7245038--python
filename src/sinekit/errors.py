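"""Exception hierarchy shared across the pipeline."""


class SinekitError(Exception):
    """Base class for all package errors."""


class InputError(SinekitError, ValueError):
    """Invalid user input (empty sequence, bad interval, unbalanced structure...)."""


class CapacityError(SinekitError):
    """The genome is too short to host the requested number of insertions."""


class InsufficientCopiesError(SinekitError):
    """Fewer genomic copies than required for consensus refinement."""


class NoElementError(SinekitError):
    """No well-supported element region found in a flanked-copy alignment."""


class ConfigError(SinekitError):
    """A pipeline configuration is missing or names an unusable input."""

    def __init__(self, key: str, message: str | None = None):
        self.key = key
        super().__init__(message or f"missing or invalid config key: {key!r}")
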