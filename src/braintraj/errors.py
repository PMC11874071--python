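"""Exception taxonomy for the pipeline.

Every stage raises one of these so callers (CLI, pipeline driver) can name the
failing stage and the kind of violation without string-matching messages.
"""


class BraintrajError(Exception):
    """Base class for all package errors."""


class FormatError(BraintrajError, ValueError):
    """A file is not in the expected on-disk format (e.g. a 3D image where 4D is required)."""


class LengthError(BraintrajError, ValueError):
    """A time series is too short for the requested computation."""


class SchemaError(BraintrajError, ValueError):
    """A table is missing a mandatory column or has an invalid layout."""


class ConsistencyError(BraintrajError, ValueError):
    """Cross-referenced inputs disagree (e.g. a label volume with ids absent from the region table)."""


class ParameterError(BraintrajError, ValueError):
    """An invalid analysis parameter (non-positive window width, scale < 1, ...)."""


class AlignmentError(BraintrajError, ValueError):
    """Spatially mismatched volumes (BOLD grid vs. parcellation grid)."""


class StageError(BraintrajError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
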