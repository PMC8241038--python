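"""Exception types shared across the pipeline."""


class PathWorkloadError(Exception):
    """Base class for all package errors."""


class ParseError(PathWorkloadError):
    """Report text does not conform to the final-report dialect."""


class ScoringError(PathWorkloadError):
    """A procedure code cannot be scored under the active config."""


class NormalizationError(PathWorkloadError):
    """A trend metric cannot be normalised (reference value is zero)."""


class AuditError(PathWorkloadError):
    """Audit sampling or accuracy computation is ill-posed."""
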