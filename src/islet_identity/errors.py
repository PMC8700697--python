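"""Exception types shared across the pipeline.

All inherit from :class:`IsletIdentityError` so callers can catch the
package's failures with a single ``except`` clause; each subclass marks a
distinct contract violation so tests (and pipelines) can react precisely.
"""


class IsletIdentityError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(IsletIdentityError):
    """A file or table violates its declared format (duplicate ids,
    dimension mismatch, non-integer counts...). The message names the
    offending record."""


class EmptyResultError(IsletIdentityError):
    """An operation produced an empty result where downstream stages
    require at least one row/cell (e.g. QC removed every cell)."""


class DegenerateCalibrationError(IsletIdentityError):
    """The two calibration reference populations have equal medians, so
    the affine rescaling of the identity score is undefined."""


class OverlappingBandsError(IsletIdentityError):
    """The beta and alpha 2-sigma bands overlap; the intermediate class
    is undefined for this configuration."""


class EmptySignatureError(IsletIdentityError):
    """None of a signature's genes are present in the matrix."""


class UndefinedScoreError(IsletIdentityError):
    """A cell has zero signal in both signatures, so its identity ratio
    is undefined."""


class StageError(IsletIdentityError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
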