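"""Exception hierarchy shared across the package.

Validation failures (bad matrices, incomplete panels, out-of-scale
judgments) and I/O failures are kept distinct so callers — in particular
the CLI — can map them to different exit codes.
"""


class McdaError(Exception):
    """Base class for all package errors."""


class ValidationError(McdaError, ValueError):
    """Input violates a structural or numerical invariant."""


class InputIOError(McdaError, OSError):
    """A file could not be read or parsed as the expected format."""
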