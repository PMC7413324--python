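"""Exception hierarchy.

All errors raised by this package derive from :class:`PesoDenoiseError`
so callers can catch everything with one clause; each also derives from
the closest built-in (``ValueError`` for bad arguments/inputs) so generic
handling keeps working.
"""


class PesoDenoiseError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(PesoDenoiseError, ValueError):
    """A parameter violates its documented precondition."""


class TooShortSignalError(InvalidArgumentError):
    """Signal shorter than the minimum required for the requested operation."""


class InvalidInputError(PesoDenoiseError, ValueError):
    """Input data is malformed (non-finite values, wrong shape, ...)."""


class NoPeakError(PesoDenoiseError, ValueError):
    """No spectral peak found at or above the requested frequency floor."""


class FilterDesignError(PesoDenoiseError, ValueError):
    """A requested IIR filter could not be designed stably.

    Usually the cutoffs are too close to 0 or Nyquist relative to the
    sampling rate; the remedy is second-order-section realisation (which
    this package already uses) or a lower order.
    """


class DegenerateWeightsError(PesoDenoiseError, ValueError):
    """Every filtered component has zero energy; weights are undefined."""


class UndefinedMetricError(PesoDenoiseError, ValueError):
    """A quality metric is undefined for the given inputs (e.g. zero-energy reference)."""
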