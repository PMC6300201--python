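"""Exception hierarchy.

Every error raised by benthoflux derives from :class:`BenthofluxError` so that
pipeline drivers can distinguish scientific QC failures from programming bugs.
"""


class BenthofluxError(Exception):
    """Base class for all benthoflux errors."""


class InvalidSampleError(BenthofluxError):
    """A gravimetric or layer sample violates its physical invariants."""


class UnknownSoluteError(BenthofluxError, KeyError):
    """Solute name not present in the diffusion-coefficient table."""


class DomainError(BenthofluxError, ValueError):
    """A scalar argument is outside its physical domain."""


class DegenerateSeriesError(BenthofluxError):
    """A time or depth series cannot support a slope estimate."""


class FlatProfileError(BenthofluxError):
    """No departure from the overlying-water plateau was found."""


class AlignmentError(BenthofluxError):
    """Two profiles that must share a grid do not."""


class InsufficientReplicationError(BenthofluxError):
    """Fewer replicates than a statistical test requires."""


class InconsistentRecordError(BenthofluxError):
    """A taxon record with biomass but zero abundance."""


class SchemaError(BenthofluxError):
    """An input table does not match its declared schema."""


class StageError(BenthofluxError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        self.detail = detail
        super().__init__(f"stage '{stage}' failed: {detail}")
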