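"""Exception hierarchy for the crop-signaling pipeline."""


class CropSignalError(Exception):
    """Base class for all package errors."""


class InvalidSensorError(CropSignalError, ValueError):
    """A sensor id outside the installed array (ids 1..6)."""


class InvalidPairError(CropSignalError, ValueError):
    """Two sensor triggers on the same detection line cannot be fused."""


class NotInvertibleError(CropSignalError, ValueError):
    """A pixel position that lies on none of the three fusion loci."""


class PreconditionError(CropSignalError, ValueError):
    """An input violating a documented precondition (e.g. unsorted events)."""


class DomainError(CropSignalError, ValueError):
    """A numeric argument outside its valid domain (e.g. zero radius)."""


class GenerationError(CropSignalError, RuntimeError):
    """Synthetic scene generation failed (e.g. plants could not be placed)."""


class ConfigError(CropSignalError, ValueError):
    """A configuration file with a missing, unknown, or ill-typed key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config key '{key}': {message}")


class DataError(CropSignalError, ValueError):
    """Unreadable or inconsistent input data (images, event streams)."""
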