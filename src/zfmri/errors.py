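"""Typed exceptions used across the package.

Every malformed input raises one of these; nothing fails silently.
"""


class ZfmriError(Exception):
    """Base class for all package errors."""


class ValidationError(ZfmriError, ValueError):
    """An input violates a documented invariant (shape, ordering, geometry...)."""


class FormatError(ZfmriError, ValueError):
    """A file on disk is structurally unreadable (missing sidecar, bad columns)."""


class DomainError(ZfmriError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class PipelineError(ZfmriError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
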