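"""Exception hierarchy.

Every failure mode that callers are expected to branch on gets its own
class; generic misuse raises ValueError as usual.
"""


class CocoaHSIError(Exception):
    """Base class for all package-specific errors."""


class EnviFormatError(CocoaHSIError):
    """Malformed or unsupported ENVI header/binary pair."""


class BandMismatchError(EnviFormatError):
    """Header band count disagrees with the binary payload or wavelength list."""


class UnsupportedInterleaveError(EnviFormatError):
    """Interleave other than BIL/BIP/BSQ."""


class CalibrationError(CocoaHSIError):
    """Reflectance calibration is ill-posed (white <= dark somewhere)."""


class SegmentationError(CocoaHSIError):
    """Bean detection failed (e.g. no objects found)."""


class PairingError(CocoaHSIError):
    """The two sides of a scan cannot be matched bean-for-bean."""


class DegenerateSpectrumError(CocoaHSIError):
    """A spectrum has no variance / zero norm where a pre-treatment needs one."""


class UnfittedError(CocoaHSIError):
    """A fit/apply operator was applied before being fitted."""


class RankError(CocoaHSIError):
    """PLS deflation exhausted the signal before the requested component count."""

    def __init__(self, msg: str, n_extracted: int):
        super().__init__(msg)
        self.n_extracted = n_extracted


class LayoutError(CocoaHSIError):
    """Synthetic scene layout is infeasible (overlap or capacity exceeded)."""


class DegenerateInputError(CocoaHSIError):
    """Statistical test input with zero variance."""


class ConfigError(CocoaHSIError):
    """Pipeline configuration schema violation."""

    def __init__(self, msg: str, keys=()):
        super().__init__(msg)
        self.keys = tuple(keys)
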