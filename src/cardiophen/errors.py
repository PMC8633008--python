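"""Exception hierarchy shared by all measurement stages."""


class CardiophenError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(CardiophenError, ValueError):
    """A synthetic-data spec violates its invariants."""


class InsufficientDataError(CardiophenError, ValueError):
    """Too few frames / samples to compute the requested quantity."""


class NonUniformSamplingError(CardiophenError, ValueError):
    """Trajectory time base is not uniform; resample before differentiating."""


class UndefinedScoreError(CardiophenError, ValueError):
    """Texture score is undefined (constant image, zero variance...)."""


class AmbiguousMaskError(CardiophenError, ValueError):
    """Cell mask contains more than one connected component."""


class EmptyMaskError(CardiophenError, ValueError):
    """Cell mask has no foreground."""


class InvalidStackError(CardiophenError, ValueError):
    """Z-stack slices disagree in shape or the stack is empty."""


class RoiOutOfBoundsError(CardiophenError, ValueError):
    """ROI polygon lies (partly) outside the image."""


class MissingBackgroundError(CardiophenError, ValueError):
    """CTF requires at least one background ROI."""


class InsufficientReplicationError(CardiophenError, ValueError):
    """A group has fewer than two observations."""


class UndefinedFoldError(CardiophenError, ZeroDivisionError):
    """Reference mean / intensity is zero."""
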