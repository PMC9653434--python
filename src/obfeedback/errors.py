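"""Exception hierarchy shared across the toolkit."""


class ObFeedbackError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ObFeedbackError, ValueError):
    """A parameter is non-finite, out of range, or inconsistent."""


class DivergenceError(ObFeedbackError, RuntimeError):
    """Numerical integration left the configured bound, naming the regime."""


class DegenerateNullclineError(ObFeedbackError, ValueError):
    """The MC nullcline is vertical (w_mc_gc = 0) and cannot be expressed as GC(MC)."""


class PairingError(ObFeedbackError, ValueError):
    """Paired per-trial vectors (or population vectors) do not match."""


class BaselineError(ObFeedbackError, ValueError):
    """A baseline (F0) window is non-positive or pathological."""


class AlignmentError(ObFeedbackError, ValueError):
    """A requested analysis window falls outside the aligned trace."""


class RoiError(ObFeedbackError, ValueError):
    """An ROI mask is empty or otherwise unusable."""
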