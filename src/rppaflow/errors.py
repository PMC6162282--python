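"""Exception hierarchy for the rppaflow pipeline.

Every stage raises a subclass of :class:`RppaFlowError`; the CLI maps
validation errors to exit code 2 and runtime stage errors to exit code 3.
"""


class RppaFlowError(Exception):
    """Base class for all rppaflow errors."""


class ValidationError(RppaFlowError):
    """Invalid arguments, parameters or configuration detected before work starts."""


class InvalidDesignError(ValidationError):
    """A synthetic-data design that cannot be generated (e.g. more planted proteins than proteins)."""


class IngestionError(RppaFlowError):
    """A malformed input file: schema violations carry row/column coordinates."""


class TransformError(RppaFlowError):
    """A numerical transform hit an invalid cell (e.g. log2 of a nonpositive value)."""


class ConfigurationError(RppaFlowError):
    """A capacity scheme or pipeline configuration is incomplete for the data at hand."""


class GenerationError(RppaFlowError):
    """Synthetic-network generation failed its structural postcondition after bounded retries."""


class StageError(RppaFlowError):
    """A pipeline stage failed; carries the stage name for the run report."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
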