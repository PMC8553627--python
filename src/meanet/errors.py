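"""Exception hierarchy shared by all stages."""


class MeanetError(Exception):
    """Base class for all package errors."""


class FormatError(MeanetError):
    """A file is structurally unreadable or misses required metadata."""


class ValidationError(MeanetError, ValueError):
    """A value violates a documented contract (range, ordering, shape)."""
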