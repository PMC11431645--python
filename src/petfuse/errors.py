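"""Exception hierarchy used across the pipeline."""


class PetfuseError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PetfuseError, ValueError):
    """A file or header is not a valid 3D image."""


class ParameterError(PetfuseError, ValueError):
    """An operation was configured with invalid parameters."""


class DegenerateInputError(PetfuseError, ValueError):
    """The input is valid but degenerate for this operation (empty mask, zero variance, ...)."""


class BoundsError(PetfuseError, ValueError):
    """A bounding box or index lies outside the parent grid."""


class AlignmentError(PetfuseError, ValueError):
    """Two volumes or tables that must share a grid / patient set do not."""


class ValidationError(PetfuseError, ValueError):
    """A clinical or configuration value fails validation."""


class NamingError(PetfuseError, ValueError):
    """Duplicate feature names after assembly."""
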