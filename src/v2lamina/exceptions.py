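"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value violates a documented precondition."""


class InputError(ValueError):
    """Input data are malformed or inconsistent (shape/label mismatches)."""


class FitError(RuntimeError):
    """A model fit failed; the payload (if any) carries diagnostics.

    Attributes
    ----------
    payload : object, optional
        Diagnostic data, e.g. the empirical curve a parametric fit could
        not reproduce.
    """

    def __init__(self, message, payload=None):
        super().__init__(message)
        self.payload = payload


class DegenerateDataWarning(UserWarning):
    """A statistic is formally defined but degenerate (e.g. zero error variance)."""
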