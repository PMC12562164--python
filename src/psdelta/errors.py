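"""Exception hierarchy with stable exit codes for the command-line layer.

Error families map to distinct process exit codes so shell callers can
distinguish I/O problems (missing/unreadable files), validation problems
(structurally invalid records), and numerical problems (non-convergence,
degenerate models).
"""


class PsdeltaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(PsdeltaError):
    """A file or path could not be read or written."""

    exit_code = 2


class ValidationError(PsdeltaError):
    """Input content violates a structural or domain invariant."""

    exit_code = 3


class NumericalError(PsdeltaError):
    """A numerical procedure failed (non-convergence, degenerate model)."""

    exit_code = 4
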