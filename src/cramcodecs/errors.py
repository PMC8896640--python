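"""Exception hierarchy shared by all codecs.

Every decoder raises :class:`CodecError` subclasses for malformed input so
callers can distinguish data errors from programming errors.  Precondition
violations on the *encoding* side (values out of range, inputs that a
transform cannot represent) raise ``ValueError`` subclasses instead.
"""


class CodecError(Exception):
    """Base class for errors raised while decoding a compressed stream."""


class TruncationError(CodecError):
    """The stream ended before the decoder expected it to."""


class MalformedError(CodecError):
    """The stream is structurally invalid (bad table, length mismatch...)."""


class UnsupportedFormatError(CodecError):
    """The stream uses flags or versions this implementation does not know."""


class NotPackableError(ValueError):
    """PACK was requested on data with more than 16 distinct symbols."""


class UnsupportedAlphabetError(ValueError):
    """Quality data uses more distinct values than the model supports."""


class InvalidNameError(ValueError):
    """A read name contains bytes the tokenizer cannot store (newline/NUL)."""
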