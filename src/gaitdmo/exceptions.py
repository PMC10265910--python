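"""Exception hierarchy for gaitdmo."""


class GaitDmoError(Exception):
    """Base class for all package errors."""


class FormatError(GaitDmoError):
    """An on-disk file does not match the expected layout."""


class DataError(GaitDmoError):
    """File parsed but contains invalid values (non-finite samples, overlaps, ...)."""


class BoundsError(GaitDmoError):
    """A requested interval lies outside the recording."""


class InsufficientEventsError(GaitDmoError):
    """Not enough events to compute the requested outcome."""


class UndefinedSymmetryError(GaitDmoError):
    """Symmetry index cannot be computed (degenerate or too-short signal)."""


class ProtocolError(GaitDmoError):
    """A simulation protocol is internally inconsistent or physically infeasible."""


class PairingError(GaitDmoError):
    """Recording/reference pairs do not line up."""
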