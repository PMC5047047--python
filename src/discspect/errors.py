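"""Exception hierarchy for discspect.

All package-raised errors derive from :class:`DiscspectError` so callers can
catch pipeline failures without masking programming errors.
"""


class DiscspectError(Exception):
    """Base class for all discspect errors."""


class InvalidParameterError(DiscspectError, ValueError):
    """A parameter violates an operation's precondition."""


class InvalidRegionError(DiscspectError, ValueError):
    """A wavenumber window selects no (or too few) channels."""


class DegenerateSpectrumError(DiscspectError, ValueError):
    """A spectrum cannot be normalized (e.g. zero norm in the window)."""


class EmptyMaskError(DiscspectError, ValueError):
    """A pixel mask retains no pixels."""


class IncompatibleImageError(DiscspectError, ValueError):
    """Images or maps have mismatching axes or grid dimensions."""


class DegenerateSectionError(DiscspectError, ValueError):
    """A section's detected tissue extent is too narrow to normalize."""


class MissingDataError(DiscspectError, ValueError):
    """Missing values inside a window that must be fully observed."""


class DegenerateDataError(DiscspectError, ValueError):
    """Constant or otherwise degenerate data passed to a statistical test."""


class DegenerateInputError(DiscspectError, ValueError):
    """An all-zero or otherwise degenerate numerical input."""


class NoDecayError(DiscspectError, ValueError):
    """An echo train does not decay; no relaxation time can be estimated."""


class NoPeakError(DiscspectError, ValueError):
    """No local maximum found inside the requested peak window."""


class IncompatibleTablesError(DiscspectError, ValueError):
    """Tables cannot be joined (empty join, duplicate keys, ...)."""


class IncompatibleRunError(DiscspectError, ValueError):
    """Samples processed under inconsistent configurations."""


class FormatError(DiscspectError, ValueError):
    """A file does not conform to the expected on-disk format."""


class PipelineStageError(DiscspectError, RuntimeError):
    """A pipeline stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, message: str, sample_id: str | None = None):
        self.stage = stage
        self.sample_id = sample_id
        suffix = f" (sample {sample_id})" if sample_id else ""
        super().__init__(f"stage '{stage}'{suffix}: {message}")
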