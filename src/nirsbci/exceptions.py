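"""Exception hierarchy shared across the pipeline stages."""


class NirsBciError(Exception):
    """Base class for all package errors."""


class InputFormatError(NirsBciError, ValueError):
    """A delimited-text input file violates the expected dialect."""


class BoundsError(NirsBciError, ValueError):
    """A requested segment exceeds the extent of the recording."""


class ParameterError(NirsBciError, ValueError):
    """A configuration value is outside its admissible range."""


class DecompositionDepthError(NirsBciError, ValueError):
    """Signal too short for the requested wavelet decomposition depth."""


class DegenerateInputError(NirsBciError, ValueError):
    """An operation received an input on which it is undefined (e.g. constant)."""


class IllConditionedError(NirsBciError, ValueError):
    """A linear system is too ill-conditioned to invert reliably."""


class ArchitectureError(NirsBciError, ValueError):
    """A network specification is inconsistent with the given input shape."""


class DivergenceError(NirsBciError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
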