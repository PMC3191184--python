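"""Exceptions and warnings raised by the analysis operations.

Degenerate inputs for which the underlying quantity is mathematically
undefined (a constant channel for a correlation, an all-zero channel for an
overlap coefficient, an empty cluster set for a percentage) are *signaled*
with a specific exception rather than silently mapped to 0 or NaN.
"""


class PunctaColocError(ValueError):
    """Base class for domain errors."""


class ConstantChannelError(PunctaColocError):
    """A correlation-type coefficient was requested on a constant channel."""


class ZeroSignalError(PunctaColocError):
    """An overlap coefficient was requested on an all-zero channel."""


class EmptyRegionError(PunctaColocError):
    """A region of interest selects no pixels of the image."""


class EmptyClusterSetError(PunctaColocError):
    """A percentage over clusters was requested with zero clusters."""


class AmbiguousLocationWarning(UserWarning):
    """A cluster centroid fell inside more than one spine perimeter."""


class PlausibilityWarning(UserWarning):
    """A geometry is outside the plausible range for traced CA1 segments."""
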