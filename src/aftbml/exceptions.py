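"""Exception types shared across the package."""


class AftBmlError(Exception):
    """Base class for package errors."""


class InvalidParameterError(AftBmlError, ValueError):
    """A configuration or prior parameter is outside its valid domain."""


class InvalidInputError(AftBmlError, ValueError):
    """Input data violates a precondition (dimensions, signs, codes)."""


class InvalidStructureError(AftBmlError, ValueError):
    """A tree structure is inconsistent with the data reaching it."""


class DegenerateDesignError(AftBmlError, ValueError):
    """A regression design is unusable (rank deficient, single action,
    no observed events)."""


class FittingError(AftBmlError, RuntimeError):
    """A numerical fitting routine failed to converge."""


class SchemaError(AftBmlError, ValueError):
    """A tabular input file violates the two-stage dataset schema."""
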