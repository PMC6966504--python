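"""Exception hierarchy shared across the package."""


class FusionTriageError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FusionTriageError):
    """A tabular input does not match its declared dialect."""


class IscnParseError(FusionTriageError):
    """A karyotype string could not be tokenized."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (offset {offset})")
        self.offset = offset


class GeneModelError(FusionTriageError):
    """A gene model violates its structural invariants."""


class CytobandMapError(FusionTriageError):
    """A cytoband table has gaps, overlaps or unparseable labels."""


class LookupError_(FusionTriageError):
    """A chromosome or symbol is absent from an index."""


class GeneratorConfigError(FusionTriageError):
    """Synthetic-cohort parameters are infeasible."""


class PipelineError(FusionTriageError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
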