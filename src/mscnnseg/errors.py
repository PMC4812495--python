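"""Exception types shared across the package."""


class MscnnsegError(Exception):
    """Base class for package errors."""


class ConfigurationError(MscnnsegError, ValueError):
    """Invalid configuration (geometry, architecture, CLI arguments)."""


class AlignmentError(MscnnsegError, ValueError):
    """Arrays that must be voxel-aligned have mismatching shapes."""


class FormatError(MscnnsegError, ValueError):
    """File content violates the expected format (e.g. label codes)."""


class DegenerateInputError(MscnnsegError, ValueError):
    """Input is degenerate for the requested operation (constant channel,
    single-class training set, ...)."""


class ShapeError(MscnnsegError, ValueError):
    """Tensor shapes incompatible with a network operation."""
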