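"""Exception hierarchy for the aorta quantification pipeline."""


class AortaQuantError(Exception):
    """Base class for all package errors."""


class SizingError(AortaQuantError):
    """Requested phantom geometry does not fit the volume bounds."""


class DomainError(AortaQuantError):
    """A query parameter lies outside its valid domain (e.g. arc length)."""


class InputError(AortaQuantError):
    """Malformed or inconsistent input data."""


class ConfigurationError(AortaQuantError):
    """Invalid or incomplete configuration."""


class NoAortaFoundError(AortaQuantError):
    """Segmentation produced an empty mask."""


class DisconnectedAortaError(AortaQuantError):
    """Centerline endpoints lie in different connected components."""


class PartitionError(AortaQuantError):
    """Projected landmarks violate the anatomical ordering."""

    def __init__(self, message: str, landmark: str | None = None):
        super().__init__(message)
        self.landmark = landmark


class TrainingError(AortaQuantError):
    """Model training diverged or received unusable data."""
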