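"""Exception types shared across the package."""


class VetpharmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(VetpharmError):
    """An input table, value or configuration failed validation."""


class TaxonomyError(VetpharmError):
    """The drug taxonomy or matching rule set is internally inconsistent."""


class UndefinedResultError(VetpharmError):
    """A statistic was requested on an empty or degenerate stratum.

    Raised instead of silently returning 0 so that "no data" is
    distinguishable from "observed zero".
    """


class PipelineStageError(VetpharmError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
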