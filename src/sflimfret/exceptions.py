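"""Toolkit-wide exception types."""


class LowSignalError(ValueError):
    """Raised when a histogram carries too few photons for a stable
    analysis (decay fit or reference-pattern extraction)."""


class FitError(RuntimeError):
    """Raised when an optimizer fails to converge; carries the best
    parameters found so far in ``best`` and a diagnostic message."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
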