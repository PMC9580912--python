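"""Exception hierarchy shared by all commkit modules."""


class CommkitError(Exception):
    """Base class for all commkit errors."""


class SchemaError(CommkitError):
    """A document does not conform to the reference-database schema."""


class IntegrityError(CommkitError):
    """A cross-reference (compound, reaction, seqid...) does not resolve."""


class ValidationError(CommkitError):
    """A query or parameter value is malformed."""


class UsageError(CommkitError):
    """An operation was invoked outside its stated preconditions."""


class InputError(CommkitError):
    """An input file has no usable content."""


class ParseError(CommkitError):
    """An input file could not be parsed."""


class GuardError(CommkitError):
    """An exhaustive computation refused to run because it would be too large."""
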