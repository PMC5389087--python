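"""Exception types shared across the pipeline stages."""


class SdscapeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(SdscapeError, ValueError):
    """A simulation or stage parameter violates its contract."""


class PlacementError(SdscapeError, RuntimeError):
    """Requested or randomised interval placement could not be satisfied."""


class CalibrationError(SdscapeError, RuntimeError):
    """Read-depth background could not be calibrated (no usable windows)."""


class LiftoverError(SdscapeError, KeyError):
    """A coordinate could not be mapped through an excision coordinate map."""


class UndefinedResultError(SdscapeError, ValueError):
    """A statistic is undefined for the given input (e.g. empty gene set)."""
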