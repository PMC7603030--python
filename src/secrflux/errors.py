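"""Exception hierarchy for the secrflux pipeline.

Callers can distinguish bad parameters (caller bugs) from degenerate data
(empty masks, flat histograms) which pipeline drivers may want to tolerate.
"""


class SecrfluxError(Exception):
    """Base class for all package errors."""


class ParameterError(SecrfluxError, ValueError):
    """A parameter violates its documented precondition."""


class InputError(SecrfluxError, ValueError):
    """Input data is malformed or inconsistent (misaligned stacks, missing
    timepoints, zero denominators)."""


class DegenerateHistogramError(SecrfluxError):
    """An intensity histogram cannot support thresholding (e.g. a constant
    image). Callers decide whether to treat this as 'nothing detected'."""


class DegenerateMaskError(SecrfluxError):
    """A segmentation step produced an empty mask where a non-empty one is
    required."""


class FitError(SecrfluxError):
    """A model fit failed to converge or returned non-finite parameters."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
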