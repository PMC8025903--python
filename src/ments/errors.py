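"""Exception hierarchy for the ments package."""


class MentsError(Exception):
    """Base class for all package-specific errors."""


class RubricValidationError(MentsError):
    """A rubric document violates the instrument's structural contract
    (wrong factor counts, duplicate scores, non-exhaustive or overlapping
    level criteria)."""


class MissingAttributeError(MentsError):
    """A case record lacks an attribute a rubric criterion needs.

    Scoring never imputes: the caller decides how to handle missing data.
    """


class ScoringError(MentsError):
    """A case could not be assigned a unique level for some factor."""


class DegenerateDataError(MentsError):
    """A reliability estimate is undefined for the given data
    (e.g. a fully constant rating matrix)."""


class SchemaError(MentsError):
    """A data file does not match the documented column schema."""
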