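"""Exception hierarchy for fibralign.

All errors raised on purpose by the package derive from :class:`FibralignError`
so callers (notably the batch runner) can separate anticipated analysis
failures from genuine bugs.
"""


class FibralignError(Exception):
    """Base class for all fibralign errors."""


class ImageInputError(FibralignError):
    """The input file could not be read or decoded as a 2D grayscale image."""


class ImageSizeError(FibralignError):
    """The image is too small for the requested crop or corner blocks."""


class ParameterError(FibralignError):
    """A configuration or operation parameter violates its constraints."""


class DegenerateSpectrumError(FibralignError):
    """The spectrum carries no usable mass (blank or noise-only image)."""


class StageError(FibralignError):
    """Wraps a failure inside the analysis pipeline with the stage name.

    The original exception is available as ``__cause__``.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
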