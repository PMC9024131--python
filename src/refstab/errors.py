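"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: schema problems (2), data-sufficiency
problems (3), I/O problems (4).
"""


class RefstabError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(RefstabError):
    """Input violates the documented table schema (missing column, bad enum...)."""

    exit_code = 2


class DuplicateRecordError(SchemaError):
    """Duplicate (sample, gene, well) row in a replicate-level table."""


class InsufficientDataError(RefstabError):
    """Too few genes, samples or replicates for the requested statistic."""

    exit_code = 3


class CalibrationError(RefstabError):
    """Between-plate calibration impossible (no shared calibrator)."""

    exit_code = 3
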