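"""Exception hierarchy.

Every failure mode that callers may want to branch on carries a short
machine-readable ``reason`` string alongside the human message.
"""


class PupillocError(Exception):
    """Base class for all package errors."""

    def __init__(self, message: str, reason: str = "error"):
        super().__init__(message)
        self.reason = reason


class ValidationError(PupillocError):
    """Invalid parameters or domain-type invariant violation."""

    def __init__(self, message: str, reason: str = "invalid-input"):
        super().__init__(message, reason)


class ExtractionError(PupillocError):
    """Eye-frame cropping failed (degenerate landmark geometry)."""

    def __init__(self, message: str, reason: str = "extraction-failed"):
        super().__init__(message, reason)


class FormatError(PupillocError):
    """Unsupported image layout or channel count."""

    def __init__(self, message: str, reason: str = "bad-format"):
        super().__init__(message, reason)


class DegenerateKernelError(PupillocError):
    """A kernel with zero variance cannot be used for normalized matching."""

    def __init__(self, message: str, reason: str = "degenerate-kernel"):
        super().__init__(message, reason)


class SizingError(PupillocError):
    """Kernel does not fit inside the (padded) frame."""

    def __init__(self, message: str, reason: str = "kernel-too-large"):
        super().__init__(message, reason)


class LocalisationError(PupillocError):
    """The matching cascade could not produce an estimate."""

    def __init__(self, message: str, reason: str = "localisation-failed"):
        super().__init__(message, reason)


class ParseError(PupillocError):
    """Malformed annotation or detection file; names file and line."""

    def __init__(self, message: str, reason: str = "parse-error"):
        super().__init__(message, reason)
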