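"""Exception hierarchy shared across the toolkit."""


class PkpdError(Exception):
    """Base class for all toolkit errors."""


class InputError(PkpdError, ValueError):
    """Invalid or insufficient input data."""


class DegenerateParameterError(PkpdError, ValueError):
    """Parameter combination for which the model form is undefined."""


class EstimationError(PkpdError, RuntimeError):
    """Estimation is impossible on the given data (e.g. no decaying phase)."""


class IntegrationError(PkpdError, RuntimeError):
    """ODE solver failed; carries solver diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}
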