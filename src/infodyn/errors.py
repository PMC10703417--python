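"""Exception hierarchy."""


class InfodynError(Exception):
    """Base class for all package-specific errors."""


class InputError(InfodynError, ValueError):
    """Malformed or inconsistent input (length mismatch, bad lags, ...)."""


class DegenerateInputError(InfodynError, ValueError):
    """Structurally valid input on which the operation is undefined
    (e.g. no valid samples after truncation, series too short to shift)."""


class UndefinedLocalError(InfodynError, ValueError):
    """A local information value was requested at an unobserved configuration."""


class UndefinedCorrelationError(InfodynError, ValueError):
    """Correlation undefined because one series has zero variance."""


class NoTransferError(InfodynError, ValueError):
    """Delay reconstruction requested with an empty source embedding."""


class ConvergenceError(InfodynError, RuntimeError):
    """Optimizer failed to reach the requested tolerance.

    The best iterate found is attached as ``.result``.
    """

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result
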