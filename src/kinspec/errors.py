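"""Exception hierarchy."""


class KinspecError(Exception):
    """Base class for all package errors."""


class MatrixNotAvailableError(KinspecError):
    """Requested substitution matrix is not bundled."""


class DatabaseFormatError(KinspecError):
    """Malformed specificity-database file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class PwmFormatError(KinspecError):
    """Malformed position-weight-matrix file."""


class SdrExtractionError(KinspecError):
    """No valid SDR string could be read for a detected kinase domain."""


class NoPrediction(KinspecError):
    """A kinase for which no prediction is possible.

    Carries a machine-readable ``reason`` and, where relevant, the number of
    matching database sites found (``n_found``).
    """

    def __init__(self, reason: str, n_found: int | None = None):
        self.reason = reason
        self.n_found = n_found
        msg = f"no prediction possible: {reason}"
        if n_found is not None:
            msg += f" ({n_found} matching sites found)"
        super().__init__(msg)
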