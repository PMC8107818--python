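"""Exception hierarchy shared across the pipeline stages."""


class QenpError(Exception):
    """Base class for all package errors."""


class FormatError(QenpError):
    """A file does not conform to its expected tabular layout."""


class ValidationError(QenpError):
    """Parsed data violates a domain invariant."""


class OutOfRangeError(QenpError):
    """A value falls outside the domain an operation is defined on."""
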