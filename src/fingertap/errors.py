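"""Exception and warning types raised across the pipeline."""


class FingertapError(Exception):
    """Base class for all errors raised by this package."""


class DegenerateProjectionError(FingertapError):
    """The thumb x-axis is (numerically) parallel to the index y-axis, so the
    projection onto the index x-z plane vanishes and the tapping angle is
    undefined."""


class CalibrationNotFoundError(FingertapError):
    """No time interval qualifies as an autocalibration window (both sensors
    vigorous and magnitude-matched for long enough)."""


class AperiodicSignalError(FingertapError):
    """The autocorrelation of the angle trace has no prominent peak in the
    admissible lag range, so no tapping period can be estimated."""


class NoTapsError(FingertapError):
    """Fewer than one complete tap could be segmented."""


class DegenerateFrameError(FingertapError):
    """Marker-board geometry is collinear or otherwise cannot define a frame."""


class PairingError(FingertapError):
    """Estimated and reference tap sets share no temporal overlap."""


class SessionFormatError(FingertapError):
    """A session file violates the documented CSV/JSON schema."""


class LowExcitationWarning(UserWarning):
    """The calibration window does not excite all three rotation axes; one
    Euler angle is weakly identifiable."""


class NoDominantAxisWarning(UserWarning):
    """Relative rotation energy is near-isotropic; realignment skipped."""
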