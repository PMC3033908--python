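"""Exception hierarchy.

Errors split into hard failures (bad inputs, impossible requests) and the
one *skip signal* (:class:`InsufficientSample`) that the scanning layer
catches and records instead of aborting a run.
"""


class GpcrMiError(Exception):
    """Base class for all package errors."""


class SchemaError(GpcrMiError):
    """A table is missing a required column or has a malformed header."""


class ReferentialError(GpcrMiError):
    """A foreign key (receptor or ligand ID) does not resolve."""


class ValidationError(GpcrMiError):
    """A cell value violates the domain contract (e.g. an excluded ligand type)."""


class AlignmentFormatError(GpcrMiError):
    """Ragged, empty or otherwise unreadable multiple sequence alignment."""


class PositionMapError(GpcrMiError):
    """Bad position map: duplicate label, malformed label, or column out of range."""


class ConfigError(GpcrMiError):
    """An invalid analysis or simulation configuration."""


class DegenerateSampleError(GpcrMiError):
    """A sample is empty (or constant where variation is required)."""


class InsufficientSample(GpcrMiError):
    """Skip signal: effective sample size below ``k_min``.

    Deliberately distinct from :class:`DegenerateSampleError` — callers that
    scan many (position, descriptor) pairs catch this, log the pair as
    skipped, and continue.
    """


class DegenerateEnsembleError(GpcrMiError):
    """All surrogates produced identical MI; the S statistic is undefined."""
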