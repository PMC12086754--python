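"""Exception hierarchy shared across the package."""


class PedrspError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PedrspError, ValueError):
    """A data file could not be parsed; the message names the offending line."""


class ValidationError(PedrspError, ValueError):
    """An object violates one of its physical or structural invariants."""


class EnergyRangeError(PedrspError, ValueError):
    """A photon energy falls outside the tabulated cross-section grid."""


class FitError(PedrspError, RuntimeError):
    """A least-squares fit could not be performed (degenerate design)."""


class CalibrationError(PedrspError, RuntimeError):
    """A calibration step failed (empty segment, non-monotone mapping, ...)."""
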