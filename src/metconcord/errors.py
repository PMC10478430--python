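"""Exception hierarchy for the pipeline.

Validation errors flag malformed input rows; domain errors flag values
outside the mathematical domain of an operation; schema errors flag
structurally unusable files.
"""


class MetconcordError(Exception):
    """Base class for all package errors."""


class SchemaError(MetconcordError):
    """A required column or field is missing from an input file."""


class ValidationError(MetconcordError):
    """An input value violates a contract (range, duplicate, label)."""


class DomainError(MetconcordError):
    """A value lies outside the mathematical domain of an operation."""


class DegenerateError(DomainError):
    """The requested statistic is undefined for this input (e.g. p0 in {0,1})."""


class FixtureLookupError(MetconcordError, KeyError):
    """An unknown packaged-fixture name was requested."""


class DesignError(MetconcordError):
    """A simulation design is internally infeasible."""
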