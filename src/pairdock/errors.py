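"""Exception hierarchy for pairdock."""


class PairdockError(Exception):
    """Base class for all pairdock errors."""


class ParseError(PairdockError):
    """A structure or table file could not be parsed."""


class EmptyStructureError(PairdockError):
    """An operation received a structure without any protein atoms."""


class CorrespondenceError(PairdockError):
    """Two structures could not be put into atom correspondence."""


class ValidationError(PairdockError):
    """An input violated a precondition (non-rigid rotation, bad spacing, ...)."""


class PotentialFormatError(ParseError):
    """A potential-table file is malformed."""


class ConstraintError(PairdockError):
    """A sampling constraint could not be satisfied within bounded retries."""
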