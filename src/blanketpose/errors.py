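"""Exception types shared across the pipeline."""


class BlanketPoseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BlanketPoseError):
    """Invalid configuration value (negative SD, bad thickness, empty dataset...)."""


class GeometryError(BlanketPoseError):
    """Scene geometry is physically impossible (surface above the camera plane)."""


class LabelError(BlanketPoseError):
    """Unknown or out-of-range posture / class label."""


class ManifestFormatError(BlanketPoseError):
    """Malformed manifest file; carries the offending row when known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class IntegrityError(BlanketPoseError):
    """Internal consistency violation (split leakage, misaligned fusion pair)."""


class InputError(BlanketPoseError):
    """Invalid runtime input (shape mismatch, weight out of range)."""
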